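import numpy as np
import pytest

from cpmkit.cpm import (
    CPMRegressor,
    correlate_edges,
    cpm_kfold,
    cpm_loocv,
    evaluate,
    fit_strength_model,
    network_strength,
    permutation_test,
    predict_score,
    select_edges,
)


class TestCorrelateEdges:
    def test_perfect_edge(self, rng):
        y = rng.standard_normal(20)
        X = np.column_stack([y, rng.standard_normal(20)])
        r, p = correlate_edges(X, y)
        assert r[0] == pytest.approx(1.0) and p[0] < 1e-15

    def test_textbook_value(self):
        # direct covariance/variance computation gives r = 0.8220
        x = np.array([[1.0], [2], [3], [4], [5]])
        y = np.array([2.0, 1, 4, 3, 6])
        r, _ = correlate_edges(x, y)
        assert r[0] == pytest.approx(0.8220, abs=1e-4)

    def test_p_matches_scipy(self, rng):
        from scipy import stats
        X = rng.standard_normal((30, 8))
        y = rng.standard_normal(30)
        r, p = correlate_edges(X, y)
        for e in range(8):
            rr, pp = stats.pearsonr(X[:, e], y)
            assert r[e] == pytest.approx(rr, abs=1e-12)
            assert p[e] == pytest.approx(pp, rel=1e-8)

    def test_orthogonal_confound_leaves_r(self, rng):
        n = 200
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 5))
        c = rng.standard_normal(n)
        # orthogonalize the confound against y and every edge
        M = np.column_stack([np.ones(n), y, X])
        c -= M @ np.linalg.lstsq(M, c, rcond=None)[0]
        r_plain, _ = correlate_edges(X, y)
        r_part, _ = correlate_edges(X, y, confounds=c)
        np.testing.assert_allclose(r_part, r_plain, atol=1e-10)

    def test_partial_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        n = 50
        df = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("xyab"))
        r, p = correlate_edges(df[["x"]].to_numpy(), df["y"].to_numpy(),
                               df[["a", "b"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["a", "b"])
        assert r[0] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p[0] == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_zero_variance_edge_flagged(self, rng):
        X = np.column_stack([np.full(10, 2.0), rng.standard_normal(10)])
        y = rng.standard_normal(10)
        with pytest.warns(UserWarning, match="zero-variance"):
            r, p = correlate_edges(X, y)
        assert r[0] == 0.0 and p[0] == 1.0

    def test_constant_scores_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            correlate_edges(rng.standard_normal((10, 3)), np.ones(10))

    def test_min_sample_guard(self, rng):
        with pytest.raises(ValueError, match="insufficient sample"):
            correlate_edges(rng.standard_normal((3, 2)), rng.standard_normal(3))


class TestSelection:
    def test_strict_threshold_and_sign_split(self):
        r = np.array([0.5, -0.5, 0.4, 0.0])
        p = np.array([0.001, 0.001, 0.01, 0.001])
        sel = select_edges(r, p, 0.01)
        np.testing.assert_array_equal(sel.pos_mask, [True, False, False, False])
        np.testing.assert_array_equal(sel.neg_mask, [False, True, False, False])

    def test_all_p_one_empty(self):
        sel = select_edges(np.array([0.9, -0.9]), np.ones(2), 0.01)
        assert not sel.pos_mask.any() and not sel.neg_mask.any()

    def test_masks_always_disjoint(self, rng):
        r = rng.uniform(-1, 1, 100)
        p = rng.uniform(0, 1, 100)
        sel = select_edges(r, p, 0.3)
        assert not (sel.pos_mask & sel.neg_mask).any()
        assert (sel.pos_mask | sel.neg_mask).sum() == ((p < 0.3) & (r != 0)).sum()


class TestStrength:
    def test_masked_sum(self):
        v = np.array([0.5, 0.25, -0.1])
        assert network_strength(v, [True, True, False]) == pytest.approx(0.75)
        assert network_strength(v, [False] * 3) == 0.0
        assert network_strength(np.array([0.1, 0.2, -0.3]), [True] * 3) == pytest.approx(0.0)

    def test_matrix_form(self, rng):
        X = rng.standard_normal((4, 6))
        mask = np.array([1, 0, 1, 0, 0, 1], bool)
        np.testing.assert_allclose(network_strength(X, mask), X[:, mask].sum(1))


class TestStrengthModel:
    def test_identity_and_negation(self, rng):
        y = rng.standard_normal(20) * 3 + 10
        m = fit_strength_model(y, y)
        assert m.slope == pytest.approx(1.0) and m.intercept == pytest.approx(0.0, abs=1e-12)
        m2 = fit_strength_model(-y, y)
        assert m2.slope == pytest.approx(-1.0)

    def test_degenerate_predicts_training_mean(self, rng):
        y = rng.standard_normal(10) + 5
        m = fit_strength_model(np.zeros(10), y)
        assert m.degenerate
        assert predict_score(m, 123.0) == pytest.approx(y.mean())

    def test_prediction_normalization(self, rng):
        s = rng.standard_normal(30) * 2 + 1
        y = rng.standard_normal(30) * 4 + 50
        m = fit_strength_model(s, y)
        # strength at the training mean -> normalized strength 0
        assert predict_score(m, m.strength_mean) == pytest.approx(
            m.intercept * m.score_sd + m.score_mean)
        # one training-sd above the mean moves the prediction by slope scorsds
        delta = predict_score(m, m.strength_mean + m.strength_sd) - predict_score(
            m, m.strength_mean)
        assert delta == pytest.approx(m.slope * m.score_sd)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_strength_model(np.arange(5.0), np.ones(5))


class TestEvaluate:
    def test_perfect_and_inverted(self, rng):
        y = rng.standard_normal(10)
        assert evaluate(y, y)[0] == pytest.approx(1.0)
        assert evaluate(-y, y)[0] == pytest.approx(-1.0)

    def test_constant_predictions_warn_zero(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            r, _ = evaluate(np.ones(10), rng.standard_normal(10))
        assert r == 0.0

    def test_orthogonal_confounds_keep_r(self, rng):
        n = 300
        a, b = rng.standard_normal((2, n))
        c = rng.standard_normal(n)
        M = np.column_stack([np.ones(n), a, b])
        c -= M @ np.linalg.lstsq(M, c, rcond=None)[0]
        r, pr = evaluate(a, b, confounds=c)
        assert pr == pytest.approx(r, abs=1e-10)


class TestCPMRegressor:
    def test_sklearn_contract(self, small_signal_data):
        from sklearn.base import clone
        ds = small_signal_data.dataset
        est = CPMRegressor(network="negative", threshold=0.05)
        assert clone(est).get_params()["threshold"] == 0.05
        est.fit(ds.edge_matrix, ds.scores)
        assert est.mask_.dtype == bool and est.n_features_in_ == ds.edge_matrix.shape[1]
        preds = est.predict(ds.edge_matrix)
        assert preds.shape == (ds.n_subjects,)
        # planted negative edges dominate the negative mask
        assert est.mask_[small_signal_data.signal_edge_idx].mean() > 0.5

    def test_training_normalization_zero_mean_unit_sd(self, small_signal_data):
        ds = small_signal_data.dataset
        est = CPMRegressor(network="negative").fit(ds.edge_matrix, ds.scores)
        s = est.network_strengths(ds.edge_matrix)
        z = (s - est.model_.strength_mean) / est.model_.strength_sd
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_gridsearch_compatible(self, small_signal_data):
        from sklearn.model_selection import GridSearchCV, KFold
        ds = small_signal_data.dataset
        gs = GridSearchCV(CPMRegressor(network="negative"),
                          {"threshold": [0.01, 0.05]},
                          cv=KFold(3), scoring="r2")
        gs.fit(ds.edge_matrix, ds.scores)
        assert set(gs.cv_results_["param_threshold"]) == {0.01, 0.05}


class TestLOOCV:
    def test_noiseless_signal_near_perfect(self):
        from cpmkit.simulate import SyntheticSpec, generate
        spec = SyntheticSpec(n_subjects=30, n_nodes=8, signal_edges=[(0, 1, -1.0)],
                             noise_sd=0.0, seed=4)
        sd = generate(spec)
        res = cpm_loocv(sd.dataset.edge_matrix, sd.dataset.scores)
        assert res["negative"].performance_r > 0.99

    def test_subject_order_invariance(self, small_signal_data, rng):
        ds = small_signal_data.dataset
        X, y = ds.edge_matrix, ds.scores
        res = cpm_loocv(X, y)
        perm = rng.permutation(len(y))
        res_p = cpm_loocv(X[perm], y[perm])
        np.testing.assert_allclose(res_p["negative"].predicted,
                                   res["negative"].predicted[perm], atol=1e-8)

    def test_guard_on_tiny_sample(self, rng):
        with pytest.raises(ValueError, match="insufficient sample"):
            cpm_loocv(rng.standard_normal((3, 4)), rng.standard_normal(3))

    def test_confound_control_runs(self, small_signal_data):
        ds = small_signal_data.dataset
        res = cpm_loocv(ds.edge_matrix, ds.scores, ds.confound_matrix())
        assert res["negative"].performance_partial_r is not None
        assert -1 <= res["negative"].performance_partial_r <= 1


class TestKFold:
    def test_k_equals_n_reduces_to_loocv(self, small_signal_data):
        ds = small_signal_data.dataset
        X, y = ds.edge_matrix, ds.scores
        loo = cpm_loocv(X, y)
        kf = cpm_kfold(X, y, k=len(y), repeats=1, seed=0)
        for sign in ("positive", "negative"):
            np.testing.assert_array_equal(kf[sign].predicted, loo[sign].predicted)

    def test_seed_determinism(self, small_signal_data):
        ds = small_signal_data.dataset
        a = cpm_kfold(ds.edge_matrix, ds.scores, k=5, repeats=3, seed=9)
        b = cpm_kfold(ds.edge_matrix, ds.scores, k=5, repeats=3, seed=9)
        assert a["negative"].performance_r == b["negative"].performance_r
        assert a["negative"].per_repeat_r == b["negative"].per_repeat_r

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            cpm_kfold(rng.standard_normal((10, 4)), rng.standard_normal(10), k=11)

    def test_noiseless_signal(self):
        from cpmkit.simulate import SyntheticSpec, generate
        spec = SyntheticSpec(n_subjects=40, n_nodes=8, signal_edges=[(0, 1, -1.0)],
                             noise_sd=0.0, seed=4)
        sd = generate(spec)
        res = cpm_kfold(sd.dataset.edge_matrix, sd.dataset.scores, k=10,
                        repeats=5, seed=1)
        assert res["negative"].performance_r > 0.99


class TestPermutation:
    def test_determinism_and_bounds(self, small_signal_data):
        ds = small_signal_data.dataset
        X, y = ds.edge_matrix, ds.scores
        res = cpm_loocv(X, y)
        obs = {"negative": res["negative"].performance_r}
        a = permutation_test(X, y, obs, n_permutations=20, seed=5)
        b = permutation_test(X, y, obs, n_permutations=20, seed=5)
        assert a["negative"].p_value == b["negative"].p_value
        assert 0 < a["negative"].p_value <= 1

    def test_strong_signal_minimal_p(self):
        from cpmkit.simulate import SyntheticSpec, generate
        spec = SyntheticSpec(n_subjects=30, n_nodes=8, signal_edges=[(0, 1, -1.0)],
                             noise_sd=0.0, seed=6)
        sd = generate(spec)
        X, y = sd.dataset.edge_matrix, sd.dataset.scores
        res = cpm_loocv(X, y)
        pt = permutation_test(X, y, {"negative": res["negative"].performance_r},
                              n_permutations=99, seed=7)
        assert pt["negative"].p_value == pytest.approx(1 / 100)
        assert pt["negative"].p_value_raw == 0.0

    def test_p_is_one_when_observed_below_null(self, small_signal_data):
        ds = small_signal_data.dataset
        X, y = ds.edge_matrix, ds.scores
        pt = permutation_test(X, y, {"negative": -2.0}, n_permutations=19, seed=1)
        assert pt["negative"].p_value == 1.0

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_test(rng.standard_normal((10, 3)), rng.standard_normal(10),
                             {"negative": 0.1}, n_permutations=0)
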