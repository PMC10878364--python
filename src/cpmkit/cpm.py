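"""Connectome-based predictive modeling (CPM).

The protocol: within each training set, correlate every connectivity edge
with the behavioral score (optionally a partial correlation controlling
confounds), keep edges with two-sided p below a threshold, split them by
correlation sign into a positive and a negative network, sum each subject's
selected edges into a network strength, fit a linear model of the
(normalized) score on the (normalized) strength, and predict held-out
subjects after normalizing their strengths with the training parameters.
Performance is the Pearson (or partial) correlation between out-of-fold
predictions and observed scores; significance comes from rerunning the whole
pipeline under permuted scores.

:class:`CPMRegressor` is the scikit-learn estimator form (one training set,
one network sign).  :func:`cpm_loocv`, :func:`cpm_kfold` and
:func:`permutation_test` drive the cross-validated protocol; they share one
fold engine, so k-fold with ``k = n`` and a single repeat reproduces
leave-one-out exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

__all__ = [
    "EdgeSelection",
    "StrengthModel",
    "CVResult",
    "PermutationResult",
    "CPMRegressor",
    "correlate_edges",
    "select_edges",
    "network_strength",
    "fit_strength_model",
    "predict_score",
    "evaluate",
    "cpm_loocv",
    "cpm_kfold",
    "permutation_test",
]

NETWORK_SIGNS = ("positive", "negative")


# ---------------------------------------------------------------------------
# edge-level statistics


def _check_confounds(confounds, n):
    if confounds is None:
        return None
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if confounds.shape[0] != n:
        raise ValueError("confounds row count does not match number of subjects")
    if not np.all(np.isfinite(confounds)):
        raise ValueError("confounds contain non-finite values")
    return confounds


def _check_min_sample(n_train, n_confounds):
    # partial-correlation degrees of freedom n - 2 - C must exceed 1
    if n_train <= n_confounds + 3:
        raise ValueError(
            f"insufficient sample for selection: training n={n_train} with "
            f"{n_confounds} confound(s) leaves no degrees of freedom"
        )


def _residualize(M, confounds):
    """Residuals of each column of M on [intercept, confounds]."""
    D = np.column_stack([np.ones(len(confounds)), confounds])
    Q, _ = np.linalg.qr(D)
    return M - Q @ (Q.T @ M)


def correlate_edges(X, y, confounds=None):
    """Per-edge (partial) Pearson correlation with the target and p-values.

    Parameters
    ----------
    X : ndarray of shape (n_subjects, n_edges)
    y : ndarray of shape (n_subjects,)
        Behavioral scores; must be nonconstant.
    confounds : ndarray of shape (n_subjects, n_confounds), optional
        When given, both each edge and the score are residualized on the
        confounds (with intercept) and the correlation of the residuals is
        returned, with p on ``n - 2 - C`` degrees of freedom; otherwise the
        plain correlation on ``n - 2`` degrees of freedom.

    Returns
    -------
    (r, p) : two ndarrays of shape (n_edges,)
        Zero-variance edges get r=0, p=1 (with a warning).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    confounds = _check_confounds(confounds, n)
    n_conf = 0 if confounds is None else confounds.shape[1]
    _check_min_sample(n, n_conf)
    if np.ptp(y) == 0:
        raise ValueError("scores are constant; correlation undefined")
    if confounds is None:
        Xr = X - X.mean(axis=0)
        yr = y - y.mean()
    else:
        Xr = _residualize(X, confounds)
        yr = _residualize(y[:, None], confounds)[:, 0]
    vx = np.einsum("ij,ij->j", Xr, Xr)
    vy = float(yr @ yr)
    scale = np.abs(X).max(axis=0, initial=0.0)
    zero = vx <= (1e-12 * np.maximum(scale, 1.0)) ** 2 * n
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance edge(s): r set to 0, p to 1",
            stacklevel=2,
        )
    denom = np.sqrt(np.where(zero, 1.0, vx) * vy)
    r = np.clip((yr @ Xr) / denom, -1.0, 1.0)
    r[zero] = 0.0
    df = n - 2 - n_conf
    p = np.ones_like(r)
    ok = ~zero
    rr = r[ok]
    with np.errstate(divide="ignore"):
        t = rr * np.sqrt(df / np.maximum(1.0 - rr * rr, 0.0))
    p[ok] = np.where(np.abs(rr) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    return r, p


@lru_cache(maxsize=None)
def _r_threshold(p_threshold: float, df: int) -> float:
    """|r| above which the two-sided p is strictly below ``p_threshold``."""
    t_crit = stats.t.isf(p_threshold / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit * t_crit))


@dataclass
class EdgeSelection:
    """Per-edge statistics and the sign-split masks from one training set."""

    edge_r: np.ndarray
    edge_p: np.ndarray
    pos_mask: np.ndarray
    neg_mask: np.ndarray
    threshold: float

    def mask(self, network: str) -> np.ndarray:
        if network not in NETWORK_SIGNS:
            raise ValueError(f"network must be one of {NETWORK_SIGNS}")
        return self.pos_mask if network == "positive" else self.neg_mask


def select_edges(edge_r, edge_p, threshold: float) -> EdgeSelection:
    """Threshold edges at strict ``p < threshold`` and split by sign of r.

    Edges with ``r == 0`` are never selected; the masks are disjoint by
    construction.
    """
    edge_r = np.asarray(edge_r, dtype=float)
    edge_p = np.asarray(edge_p, dtype=float)
    if edge_r.shape != edge_p.shape:
        raise ValueError("edge_r and edge_p must be aligned")
    sig = edge_p < threshold
    return EdgeSelection(
        edge_r=edge_r,
        edge_p=edge_p,
        pos_mask=sig & (edge_r > 0),
        neg_mask=sig & (edge_r < 0),
        threshold=threshold,
    )


def network_strength(edge_values, mask):
    """Sum of selected edge values; one number per subject (0 if mask empty)."""
    edge_values = np.asarray(edge_values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if edge_values.shape[-1] != mask.shape[0]:
        raise ValueError("edge values and mask are not aligned")
    return edge_values[..., mask].sum(axis=-1)


# ---------------------------------------------------------------------------
# strength model

_DEGENERATE_SD = 1e-12


@dataclass
class StrengthModel:
    """Linear fit of normalized score on normalized network strength.

    Normalization parameters (mean/sd of strength and score) come from the
    training set and are reused verbatim at prediction time.  A degenerate
    model (constant training strengths, e.g. an empty mask) predicts the
    training-mean score.
    """

    slope: float
    intercept: float
    strength_mean: float
    strength_sd: float
    score_mean: float
    score_sd: float
    degenerate: bool = False


def fit_strength_model(strengths, scores) -> StrengthModel:
    """OLS of z-scored training score on z-scored training strength."""
    s = np.asarray(strengths, dtype=float)
    y = np.asarray(scores, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("strengths and scores must be aligned 1-D arrays")
    if len(s) < 3:
        raise ValueError("need at least 3 training subjects")
    mu_y, sd_y = y.mean(), y.std(ddof=1)
    if sd_y == 0:
        raise ValueError("scores are constant; model undefined")
    mu_s, sd_s = s.mean(), s.std(ddof=1)
    if sd_s <= _DEGENERATE_SD:
        return StrengthModel(0.0, 0.0, mu_s, 1.0, mu_y, sd_y, degenerate=True)
    zs = (s - mu_s) / sd_s
    zy = (y - mu_y) / sd_y
    zs_c = zs - zs.mean()
    slope = float((zs_c @ zy) / (zs_c @ zs_c))
    intercept = float(zy.mean() - slope * zs.mean())
    return StrengthModel(slope, intercept, mu_s, sd_s, mu_y, sd_y)


def predict_score(model: StrengthModel, strength):
    """Predict raw-scale scores from raw network strengths."""
    strength = np.asarray(strength, dtype=float)
    if model.degenerate:
        out = np.full(strength.shape, model.score_mean)
        return float(out) if out.ndim == 0 else out
    z = (strength - model.strength_mean) / model.strength_sd
    out = (model.slope * z + model.intercept) * model.score_sd + model.score_mean
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# evaluation


def _pearson(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean()
    bc = b - b.mean()
    va = float(ac @ ac)
    vb = float(bc @ bc)
    if va == 0 or vb == 0:
        return None
    return float(np.clip((ac @ bc) / np.sqrt(va * vb), -1.0, 1.0))


def evaluate(predicted, observed, confounds=None):
    """Model performance: Pearson r and, with confounds, the partial r.

    The partial correlation residualizes both the predictions and the
    observed scores on the confounds (with intercept) before correlating.
    A constant prediction vector yields r = 0 with a warning.

    Returns
    -------
    (r, partial_r) : (float, float or None)
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must be aligned")
    if len(predicted) < 3:
        raise ValueError("correlation undefined: need at least 3 subjects")
    if np.ptp(observed) == 0:
        raise ValueError("observed scores are constant")
    r = _pearson(predicted, observed)
    if r is None:
        warnings.warn("constant predictions: r reported as 0", stacklevel=2)
        r = 0.0
    if confounds is None:
        return r, None
    confounds = _check_confounds(confounds, len(predicted))
    pr = _residualize(predicted[:, None], confounds)[:, 0]
    orr = _residualize(observed[:, None], confounds)[:, 0]
    partial = _pearson(pr, orr)
    if partial is None:
        warnings.warn("constant residualized predictions: partial r reported as 0",
                      stacklevel=2)
        partial = 0.0
    return r, partial


# ---------------------------------------------------------------------------
# scikit-learn estimator


class CPMRegressor(RegressorMixin, BaseEstimator):
    """One-shot CPM estimator: select edges, sum a network, fit, predict.

    Parameters
    ----------
    network : {"negative", "positive"}
        Which sign-split edge network drives the prediction.
    threshold : float
        Two-sided p-value threshold for edge selection (strict ``<``).
    normalize_edges : bool
        When True, edges are z-scored with training parameters before the
        strength sum (selection is unaffected: Pearson correlation is
        invariant to affine rescaling).

    Attributes
    ----------
    selection_ : EdgeSelection
        Training-set edge statistics and masks (both signs).
    mask_ : ndarray of bool
        The active network's edge mask.
    model_ : StrengthModel
        Fitted normalization parameters and linear coefficients.
    n_features_in_ : int
    """

    def __init__(self, network: str = "negative", threshold: float = 0.01,
                 normalize_edges: bool = False):
        self.network = network
        self.threshold = threshold
        self.normalize_edges = normalize_edges

    def fit(self, X, y, confounds=None):
        if self.network not in NETWORK_SIGNS:
            raise ValueError(f"network must be one of {NETWORK_SIGNS}")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        X, y = check_X_y(X, y, y_numeric=True)
        r, p = correlate_edges(X, y, confounds)
        self.selection_ = select_edges(r, p, self.threshold)
        self.mask_ = self.selection_.mask(self.network)
        self.n_features_in_ = X.shape[1]
        if self.normalize_edges:
            self.edge_mean_ = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1)
            self.edge_sd_ = np.where(sd > 0, sd, 1.0)
            Xn = (X - self.edge_mean_) / self.edge_sd_
        else:
            Xn = X
        strengths = network_strength(Xn, self.mask_)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.model_ = fit_strength_model(strengths, y)
        if self.model_.degenerate:
            warnings.warn(
                f"degenerate {self.network}-network model (empty or constant "
                "strength): predicting the training mean", stacklevel=2)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} edges, expected {self.n_features_in_}")
        if self.normalize_edges:
            X = (X - self.edge_mean_) / self.edge_sd_
        return predict_score(self.model_, network_strength(X, self.mask_))

    def network_strengths(self, X):
        """Raw (or training-normalized) strengths for the fitted mask."""
        check_is_fitted(self, "mask_")
        X = check_array(X)
        if self.normalize_edges:
            X = (X - self.edge_mean_) / self.edge_sd_
        return network_strength(X, self.mask_)


# ---------------------------------------------------------------------------
# cross-validation engine


@dataclass
class CVResult:
    """Out-of-fold predictions and performance for one network sign."""

    network: str
    predicted: np.ndarray
    observed: np.ndarray
    performance_r: float
    performance_partial_r: float | None
    fold_masks: np.ndarray | None  # (n_folds, n_edges) bool, fold order
    fold_models: list[StrengthModel] | None
    fold_mask_sizes: list[int]
    n_degenerate_folds: int
    scheme: str
    k: int | None = None
    repeats: int = 1
    seed: int | None = None
    per_repeat_r: list[float] | None = None
    permutation_p: float | None = None
    permutation_p_raw: float | None = None
    null_distribution: np.ndarray | None = field(default=None, repr=False)


def _fold_stats_plain(Xc, yc, sums, test_idx):
    """Training-set Pearson r by downdating whole-sample sums.

    ``Xc``/``yc`` are globally centered copies (centering leaves every
    training-fold correlation unchanged but conditions the sums).
    """
    Sx, Sxx, Sxy, Sy, Syy, n = sums
    Xf = Xc[test_idx]
    yf = yc[test_idx]
    nt = n - len(test_idx)
    sx = Sx - Xf.sum(axis=0)
    sxx = Sxx - np.einsum("ij,ij->j", Xf, Xf)
    sxy = Sxy - yf @ Xf
    sy = Sy - float(yf.sum())
    syy = Syy - float(yf @ yf)
    num = nt * sxy - sx * sy
    varx = np.maximum(nt * sxx - sx * sx, 0.0)
    vary = max(nt * syy - sy * sy, 0.0)
    if vary == 0:
        raise ValueError("scores constant within a training fold")
    zero = varx <= 1e-10
    denom = np.sqrt(np.where(zero, 1.0, varx) * vary)
    r = np.clip(num / denom, -1.0, 1.0)
    r[zero] = 0.0
    return r, nt


def _fold_stats_partial(X, y, confounds, train_idx):
    """Training-set partial correlation by direct residualization."""
    Xt = X[train_idx]
    yt = y[train_idx]
    Ct = confounds[train_idx]
    if np.ptp(yt) == 0:
        raise ValueError("scores constant within a training fold")
    Xr = _residualize(Xt, Ct)
    yr = _residualize(yt[:, None], Ct)[:, 0]
    vx = np.einsum("ij,ij->j", Xr, Xr)
    vy = float(yr @ yr)
    zero = vx <= 1e-10
    denom = np.sqrt(np.where(zero, 1.0, vx) * vy)
    r = np.clip((yr @ Xr) / denom, -1.0, 1.0)
    r[zero] = 0.0
    return r, len(train_idx)


def _run_loo_fast(X, y, subject_order, threshold, normalize_edges, keep_masks):
    """Vectorized leave-one-out pass (no confounds).

    Training correlations for every fold come from downdating the
    whole-sample sums in one broadcast step; strengths are gathered per
    fold over the few selected columns.  ``subject_order[f]`` is the
    subject left out by fold ``f``.
    """
    n, n_edges_ = X.shape
    nt = n - 1
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = Xc.sum(axis=0) - Xc
    sxx = np.einsum("ij,ij->j", Xc, Xc) - Xc * Xc
    sxy = (yc @ Xc) - yc[:, None] * Xc
    sy = float(yc.sum()) - yc
    syy = float(yc @ yc) - yc * yc
    vary = np.maximum(nt * syy - sy * sy, 0.0)
    if np.any(vary == 0):
        raise ValueError("scores constant within a training fold")
    num = nt * sxy - sx * sy[:, None]
    varx = np.maximum(nt * sxx - sx * sx, 0.0)
    zero = varx <= 1e-10
    denom = np.sqrt(np.where(zero, 1.0, varx) * vary[:, None])
    r = np.clip(num / denom, -1.0, 1.0)
    r[zero] = 0.0
    r_crit = _r_threshold(threshold, nt - 2)
    pos = r > r_crit
    neg = r < -r_crit

    predicted = {s: np.empty(n) for s in NETWORK_SIGNS}
    masks = {s: (np.zeros((n, n_edges_), dtype=bool) if keep_masks else None)
             for s in NETWORK_SIGNS}
    models = {s: [] for s in NETWORK_SIGNS}
    mask_sizes = {s: [] for s in NETWORK_SIGNS}
    degenerate = {s: 0 for s in NETWORK_SIGNS}

    if keep_masks or normalize_edges:
        # full path: per-fold StrengthModel objects are retained
        tr = np.ones(n, dtype=bool)
        for f_i, i in enumerate(subject_order):
            tr[i] = False
            y_tr = y[tr]
            for sign, mrow in (("positive", pos[i]), ("negative", neg[i])):
                if keep_masks:
                    masks[sign][f_i] = mrow
                idx = np.flatnonzero(mrow)
                mask_sizes[sign].append(int(idx.size))
                if idx.size:
                    sel = X[:, idx]
                    if normalize_edges:
                        mu = sel[tr].mean(axis=0)
                        sd = sel[tr].std(axis=0, ddof=1)
                        sel = (sel - mu) / np.where(sd > 0, sd, 1.0)
                    s_all = sel.sum(axis=1)
                else:
                    s_all = np.zeros(n)
                model = fit_strength_model(s_all[tr], y_tr)
                if model.degenerate:
                    degenerate[sign] += 1
                models[sign].append(model)
                predicted[sign][i] = predict_score(model, s_all[i])
            tr[i] = True
        return predicted, masks, models, mask_sizes, degenerate

    # lean path (permutations): identical algebra, fits vectorized across
    # folds from per-fold sufficient statistics; no model objects built
    Y1 = float(y.sum()) - y
    Y2 = float(y @ y) - y * y
    mu_y = Y1 / nt
    sd_y = np.sqrt(np.maximum((Y2 - Y1 * Y1 / nt) / (nt - 1), 0.0))
    for sign, sel_rows in (("positive", pos), ("negative", neg)):
        s_i = np.zeros(n)
        st1 = np.zeros(n)
        st2 = np.zeros(n)
        sty = np.zeros(n)
        sizes = mask_sizes[sign]
        for i in subject_order:
            idx = np.flatnonzero(sel_rows[i])
            sizes.append(int(idx.size))
            if idx.size:
                s_all = X[:, idx].sum(axis=1)
                tot1 = float(s_all.sum())
                tot2 = float(s_all @ s_all)
                toty = float(s_all @ y)
                s_i[i] = s_all[i]
                st1[i] = tot1 - s_all[i]
                st2[i] = tot2 - s_all[i] * s_all[i]
                sty[i] = toty - s_all[i] * y[i]
        mu_s = st1 / nt
        var_s = np.maximum((st2 - st1 * st1 / nt) / (nt - 1), 0.0)
        sd_s = np.sqrt(var_s)
        degen = sd_s <= _DEGENERATE_SD
        sd_safe = np.where(degen, 1.0, sd_s)
        cov = (sty - st1 * Y1 / nt) / (nt - 1)
        slope_z = cov / (sd_safe * sd_y)  # OLS slope in normalized space
        pred = (slope_z * (s_i - mu_s) / sd_safe) * sd_y + mu_y
        predicted[sign] = np.where(degen, mu_y, pred)
        degenerate[sign] = int(degen.sum())
    return predicted, masks, models, mask_sizes, degenerate


def _run_folds(X, y, folds, threshold, confounds=None, normalize_edges=False,
               keep_masks=True):
    """Run the full CPM protocol over a fold partition; both network signs.

    Returns per-sign out-of-fold predictions plus per-fold masks, models and
    degeneracy counts.  This is the single engine behind LOOCV and k-fold:
    singleton folds without confounds dispatch to the vectorized
    leave-one-out pass, so k-fold with k = n reproduces LOOCV exactly.
    """
    n, n_edges_ = X.shape
    n_conf = 0 if confounds is None else confounds.shape[1]
    min_train = min(n - len(f) for f in folds)
    _check_min_sample(min_train, n_conf)

    if confounds is None and all(len(f) == 1 for f in folds):
        order = np.array([f[0] for f in folds])
        return _run_loo_fast(X, y, order, threshold, normalize_edges, keep_masks)

    if confounds is None:
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sums = (
            Xc.sum(axis=0),
            np.einsum("ij,ij->j", Xc, Xc),
            yc @ Xc,
            float(yc.sum()),
            float(yc @ yc),
            n,
        )
    all_idx = np.arange(n)
    predicted = {s: np.empty(n) for s in NETWORK_SIGNS}
    masks = {s: (np.zeros((len(folds), n_edges_), dtype=bool) if keep_masks else None)
             for s in NETWORK_SIGNS}
    models = {s: [] for s in NETWORK_SIGNS}
    mask_sizes = {s: [] for s in NETWORK_SIGNS}
    degenerate = {s: 0 for s in NETWORK_SIGNS}

    for f_i, test_idx in enumerate(folds):
        if confounds is None:
            r, nt = _fold_stats_plain(Xc, yc, sums, test_idx)
            df = nt - 2
        else:
            train_idx = np.setdiff1d(all_idx, test_idx, assume_unique=True)
            r, nt = _fold_stats_partial(X, y, confounds, train_idx)
            df = nt - 2 - n_conf
        if confounds is None:
            train_idx = np.setdiff1d(all_idx, test_idx, assume_unique=True)
        r_crit = _r_threshold(threshold, df)
        fold_masks = {"positive": r > r_crit, "negative": r < -r_crit}
        for sign in NETWORK_SIGNS:
            m = fold_masks[sign]
            if keep_masks:
                masks[sign][f_i] = m
            mask_sizes[sign].append(int(m.sum()))
            sel = X[:, m]
            if normalize_edges:
                mu = sel[train_idx].mean(axis=0) if m.any() else 0.0
                sd = sel[train_idx].std(axis=0, ddof=1) if m.any() else 1.0
                sd = np.where(sd > 0, sd, 1.0) if m.any() else sd
                sel = (sel - mu) / sd
            s_all = sel.sum(axis=1)
            model = fit_strength_model(s_all[train_idx], y[train_idx])
            if model.degenerate:
                degenerate[sign] += 1
            models[sign].append(model)
            predicted[sign][test_idx] = predict_score(model, s_all[test_idx])
    return predicted, masks, models, mask_sizes, degenerate


def _loo_folds(n):
    return [np.array([i]) for i in range(n)]


def _kfold_folds(n, k, random_state):
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=random_state)
    return [test for _, test in kf.split(np.empty((n, 1)))]


def _prepare_xy(X, y, confounds):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != len(y):
        raise ValueError("X must be (n_subjects, n_edges) aligned with y")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    return X, y, _check_confounds(confounds, len(y))


def cpm_loocv(X, y, confounds=None, threshold=0.01, normalize_edges=False,
              keep_masks=True):
    """Leave-one-out CPM: each subject predicted from all others.

    Selection, strength summation, normalization and the linear fit are
    redone inside every fold; per-fold masks are retained so the
    contributing network (their intersection) can be formed.

    Returns
    -------
    dict of {"positive": CVResult, "negative": CVResult}
    """
    X, y, confounds = _prepare_xy(X, y, confounds)
    folds = _loo_folds(len(y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        predicted, masks, models, sizes, degen = _run_folds(
            X, y, folds, threshold, confounds, normalize_edges, keep_masks)
    out = {}
    for sign in NETWORK_SIGNS:
        r, pr = evaluate(predicted[sign], y, confounds)
        out[sign] = CVResult(
            network=sign, predicted=predicted[sign], observed=y.copy(),
            performance_r=r, performance_partial_r=pr,
            fold_masks=masks[sign], fold_models=models[sign],
            fold_mask_sizes=sizes[sign], n_degenerate_folds=degen[sign],
            scheme="loo",
        )
    return out


def cpm_kfold(X, y, confounds=None, threshold=0.01, k=10, repeats=100,
              seed=0, normalize_edges=False):
    """Repeated k-fold CPM with seeded random partitions.

    Per repeat, the pooled out-of-fold predictions are correlated with the
    observed scores; the reported performance is the mean (partial) r across
    repeats, and the reported predictions are the per-subject means.  Fold
    masks are retained only for a single repeat (``repeats=1``), where the
    contributing network is well defined.
    """
    X, y, confounds = _prepare_xy(X, y, confounds)
    n = len(y)
    rng = np.random.default_rng(seed)
    keep = repeats == 1
    r_list, pr_list = [], []
    pred_sum = {s: np.zeros(n) for s in NETWORK_SIGNS}
    kept_masks = {s: None for s in NETWORK_SIGNS}
    kept_models = {s: None for s in NETWORK_SIGNS}
    kept_sizes = {s: [] for s in NETWORK_SIGNS}
    degen_total = {s: 0 for s in NETWORK_SIGNS}
    for _ in range(repeats):
        folds = _kfold_folds(n, k, int(rng.integers(2**31 - 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            predicted, masks, models, sizes, degen = _run_folds(
                X, y, folds, threshold, confounds, normalize_edges, keep)
        rep_r, rep_pr = {}, {}
        for sign in NETWORK_SIGNS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep_r[sign], rep_pr[sign] = evaluate(predicted[sign], y, confounds)
            pred_sum[sign] += predicted[sign]
            degen_total[sign] += degen[sign]
            kept_sizes[sign].extend(sizes[sign])
            if keep:
                kept_masks[sign] = masks[sign]
                kept_models[sign] = models[sign]
        r_list.append(rep_r)
        pr_list.append(rep_pr)
    out = {}
    for sign in NETWORK_SIGNS:
        per_rep = [d[sign] for d in r_list]
        per_rep_pr = [d[sign] for d in pr_list]
        out[sign] = CVResult(
            network=sign, predicted=pred_sum[sign] / repeats, observed=y.copy(),
            performance_r=float(np.mean(per_rep)),
            performance_partial_r=(None if confounds is None
                                   else float(np.mean(per_rep_pr))),
            fold_masks=kept_masks[sign], fold_models=kept_models[sign],
            fold_mask_sizes=kept_sizes[sign],
            n_degenerate_folds=degen_total[sign],
            scheme="kfold", k=k, repeats=repeats, seed=seed,
            per_repeat_r=[float(v) for v in per_rep],
        )
    return out


@dataclass
class PermutationResult:
    """Permutation-test outcome for one network sign."""

    p_value: float          # add-one corrected: (#{r_perm >= r_obs} + 1) / (m + 1)
    p_value_raw: float      # plain proportion #{r_perm >= r_obs} / m
    observed_r: float
    null_distribution: np.ndarray
    n_permutations: int
    seed: int


def permutation_test(X, y, observed_r, confounds=None, threshold=0.01,
                     scheme="loo", k=10, kfold_repeats=10, n_permutations=1000,
                     seed=0, normalize_edges=False):
    """Permutation inference: rerun the whole CV pipeline under shuffled scores.

    Scores are permuted across subjects while edges and confounds stay
    attached to their subjects; selection, model fitting and evaluation are
    redone per permutation (partial correlations are recomputed when
    confounds are given).  Ties count against the observed statistic
    (``>=``), and the reported p uses the add-one correction
    ``(b + 1) / (m + 1)``; the raw proportion is kept alongside.

    Parameters
    ----------
    observed_r : dict mapping network sign to the unpermuted performance,
        e.g. ``{"negative": 0.2}``; only the listed signs are tested.
    scheme : {"loo", "kfold"}
        k-fold permutations run the repeated procedure with
        ``kfold_repeats`` repeats per permutation.

    Returns
    -------
    dict of {sign: PermutationResult}
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X, y, confounds = _prepare_xy(X, y, confounds)
    signs = tuple(observed_r)
    for s in signs:
        if s not in NETWORK_SIGNS:
            raise ValueError(f"unknown network sign {s!r}")
    rng = np.random.default_rng(seed)
    null = {s: np.empty(n_permutations) for s in signs}
    n = len(y)
    for i in range(n_permutations):
        y_perm = y[rng.permutation(n)]
        if scheme == "loo":
            folds = _loo_folds(n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                predicted, *_ = _run_folds(
                    X, y_perm, folds, threshold, confounds, normalize_edges,
                    keep_masks=False)
            for s in signs:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, pr = evaluate(predicted[s], y_perm, confounds)
                null[s][i] = r if confounds is None else pr
        elif scheme == "kfold":
            res = cpm_kfold(X, y_perm, confounds, threshold, k=k,
                            repeats=kfold_repeats,
                            seed=int(rng.integers(2**31 - 1)),
                            normalize_edges=normalize_edges)
            for s in signs:
                cv = res[s]
                null[s][i] = (cv.performance_r if confounds is None
                              else cv.performance_partial_r)
        else:
            raise ValueError("scheme must be 'loo' or 'kfold'")
    out = {}
    for s in signs:
        b = int(np.sum(null[s] >= observed_r[s]))
        out[s] = PermutationResult(
            p_value=(b + 1) / (n_permutations + 1),
            p_value_raw=b / n_permutations,
            observed_r=float(observed_r[s]),
            null_distribution=null[s],
            n_permutations=n_permutations,
            seed=seed,
        )
    return out
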