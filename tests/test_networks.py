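import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpmkit.connectome import n_edges
from cpmkit.networks import (
    ContributingNetwork,
    compare_networks,
    contributing_network,
    macroscale_counts,
    node_strength,
)
from cpmkit.simulate import SHEN268_MACROSCALE_COUNTS, make_atlas

N_NODES = 8
E = n_edges(N_NODES)


def _net(mask, weights=None):
    if weights is None:
        weights = np.linspace(-1, 1, E)
    return ContributingNetwork(mask, weights, N_NODES, n_folds=1)


class TestContributing:
    def test_intersection_is_and(self, rng):
        masks = rng.random((5, E)) < 0.5
        net = contributing_network(masks, np.zeros(E), N_NODES)
        np.testing.assert_array_equal(net.edge_mask, masks.all(0))

    def test_single_fold_identity(self, rng):
        m = rng.random(E) < 0.4
        net = contributing_network(m[None, :], np.zeros(E), N_NODES)
        np.testing.assert_array_equal(net.edge_mask, m)

    def test_missing_edge_excluded(self):
        masks = np.ones((3, E), bool)
        masks[1, 4] = False
        net = contributing_network(masks, np.zeros(E), N_NODES)
        assert not net.edge_mask[4] and net.edge_mask.sum() == E - 1

    def test_monotone_in_folds(self, rng):
        masks = rng.random((6, E)) < 0.7
        sizes = [contributing_network(masks[:k], np.zeros(E), N_NODES).edge_mask.sum()
                 for k in range(1, 7)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            contributing_network(np.ones((2, E + 1), bool), np.zeros(E), N_NODES)


class TestNodeStrength:
    def test_incident_absolute_sum(self):
        mask = np.zeros(E, bool)
        w = np.zeros(E)
        # edges (0,1) and (0,2) in canonical order are positions 0 and 1
        mask[[0, 1]] = True
        w[[0, 1]] = [-0.3, -0.2]
        table = node_strength(_net(mask, w)).set_index("node_id")
        assert table.loc[0, "strength"] == pytest.approx(0.5)
        assert table.loc[0, "signed_strength"] == pytest.approx(-0.5)
        assert table.loc[1, "strength"] == pytest.approx(0.3)

    def test_empty_network_all_zero(self):
        table = node_strength(_net(np.zeros(E, bool)))
        assert (table["strength"] == 0).all()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_handshake_identity(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random(E) < 0.5
        w = rng.standard_normal(E)
        net = _net(mask, w)
        table = node_strength(net)
        assert table["strength"].sum() == pytest.approx(
            2 * np.abs(w[mask]).sum(), rel=1e-12)

    def test_descending_rank(self, rng):
        table = node_strength(_net(rng.random(E) < 0.6, rng.standard_normal(E)))
        assert (np.diff(table["strength"]) <= 1e-15).all()
        assert list(table["rank"]) == list(range(1, N_NODES + 1))


class TestMacroscale:
    def test_single_cross_region_edge(self):
        atlas = make_atlas(268)
        n268 = 268
        e268 = n_edges(n268)
        mask = np.zeros(e268, bool)
        # edge between node 0 (prefrontal) and node 267 (brainstem): last
        # column of row 0 in the upper triangle
        mask[266] = True
        net = ContributingNetwork(mask, np.ones(e268), n268, 1)
        counts = macroscale_counts(net, atlas)
        assert counts.loc["prefrontal", "brainstem"] == 1
        assert counts.loc["brainstem", "prefrontal"] == 1
        assert counts.to_numpy().sum() == 2  # one off-diagonal pair

    def test_within_region_on_diagonal(self):
        atlas = make_atlas(268)
        mask = np.zeros(n_edges(268), bool)
        mask[0] = True  # nodes 0 and 1, both prefrontal
        net = ContributingNetwork(mask, np.ones(n_edges(268)), 268, 1)
        counts = macroscale_counts(net, atlas)
        assert counts.loc["prefrontal", "prefrontal"] == 1

    def test_total_count_conserved(self, rng):
        atlas = make_atlas(N_NODES)
        mask = rng.random(E) < 0.5
        counts = macroscale_counts(_net(mask), atlas)
        upper = np.triu(counts.to_numpy())
        assert upper.sum() == mask.sum()

    def test_reference_grouping_sums_to_268(self):
        assert tuple(SHEN268_MACROSCALE_COUNTS.values()) == (
            46, 21, 7, 27, 39, 25, 36, 41, 17, 9)
        assert sum(SHEN268_MACROSCALE_COUNTS.values()) == 268
        atlas = make_atlas(268)
        counts = atlas.groupby("macroscale_region").size()
        assert counts.sum() == 268
        for region, n in SHEN268_MACROSCALE_COUNTS.items():
            assert counts[region] == n


def test_macroscale_heatmap_written(tmp_path, rng):
    from cpmkit.networks import plot_macroscale_counts
    counts = macroscale_counts(_net(rng.random(E) < 0.5), make_atlas(N_NODES))
    out = tmp_path / "counts.png"
    plot_macroscale_counts(counts, out, title="edge counts")
    assert out.stat().st_size > 0


class TestCompare:
    def test_identical_masks(self, rng):
        m = rng.random(E) < 0.5
        cmp_ = compare_networks(_net(m), _net(m))
        assert cmp_.shared_count == m.sum()
        assert not cmp_.unique_a.any() and not cmp_.unique_b.any()

    def test_disjoint_masks(self):
        a = np.zeros(E, bool)
        b = np.zeros(E, bool)
        a[:3] = True
        b[3:6] = True
        cmp_ = compare_networks(_net(a), _net(b))
        assert cmp_.shared_count == 0
        assert cmp_.unique_a.sum() == 3 and cmp_.unique_b.sum() == 3

    def test_partition_identity(self):
        a = np.zeros(E, bool)
        b = np.zeros(E, bool)
        a[:5] = True
        b[3:7] = True
        cmp_ = compare_networks(_net(a), _net(b))
        assert cmp_.shared_count == 2
        assert cmp_.unique_a.sum() == 3
        assert cmp_.shared_count + cmp_.unique_a.sum() == a.sum()

    def test_symmetry_under_swap(self, rng):
        a = rng.random(E) < 0.5
        b = rng.random(E) < 0.5
        c1 = compare_networks(_net(a), _net(b))
        c2 = compare_networks(_net(b), _net(a))
        np.testing.assert_array_equal(c1.unique_a, c2.unique_b)
        assert c1.shared_count == c2.shared_count

    def test_different_spaces_rejected(self):
        small = ContributingNetwork(np.zeros(3, bool), np.zeros(3), 3, 1)
        with pytest.raises(ValueError):
            compare_networks(_net(np.zeros(E, bool)), small)
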