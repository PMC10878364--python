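"""Characterizing the predictive network.

The contributing network is the set of edges selected in *every*
cross-validation fold.  It is summarised by per-node strength (sum of
absolute edge weights incident to a node), by counts of edges within and
between ten macroscale brain regions, and by overlap comparison against the
contributing network of a different behavioral outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import edge_node_pairs, n_edges
from .io import MACROSCALE_REGIONS


@dataclass
class ContributingNetwork:
    """Across-fold edge intersection with per-edge correlation weights.

    ``edge_weight`` holds the full-sample (partial) correlation between each
    edge and the target; only entries under ``edge_mask`` are meaningful.
    """

    edge_mask: np.ndarray
    edge_weight: np.ndarray
    n_nodes: int
    n_folds: int

    def __post_init__(self):
        self.edge_mask = np.asarray(self.edge_mask, dtype=bool)
        self.edge_weight = np.asarray(self.edge_weight, dtype=float)
        if self.edge_mask.shape != self.edge_weight.shape:
            raise ValueError("edge_mask and edge_weight must be aligned")
        if self.edge_mask.shape[0] != n_edges(self.n_nodes):
            raise ValueError("mask length does not match n_nodes")
        if not np.all(np.isfinite(self.edge_weight[self.edge_mask])):
            raise ValueError("non-finite weight on a masked edge")

    @property
    def n_edges_selected(self) -> int:
        return int(self.edge_mask.sum())


def contributing_network(fold_masks, edge_weights, n_nodes: int) -> ContributingNetwork:
    """Intersect per-fold edge masks (elementwise AND) and attach weights.

    Parameters
    ----------
    fold_masks : (n_folds, n_edges) boolean array or list of 1-D masks
    edge_weights : per-edge full-sample correlations with the target
    """
    fold_masks = np.atleast_2d(np.asarray(fold_masks, dtype=bool))
    if fold_masks.shape[0] < 1:
        raise ValueError("need at least one fold mask")
    edge_weights = np.asarray(edge_weights, dtype=float)
    if fold_masks.shape[1] != edge_weights.shape[0]:
        raise ValueError(
            f"fold masks have {fold_masks.shape[1]} edges but weights have "
            f"{edge_weights.shape[0]}")
    return ContributingNetwork(
        edge_mask=fold_masks.all(axis=0),
        edge_weight=edge_weights,
        n_nodes=n_nodes,
        n_folds=fold_masks.shape[0],
    )


def node_strength(net: ContributingNetwork) -> pd.DataFrame:
    """Per-node strength: sum of |weight| over incident contributing edges.

    Also emits the signed sum for transparency.  Rows are sorted by
    descending strength with ties kept in node order; ``rank`` is 1-based.
    Isolated nodes have strength 0.
    """
    iu, ju = edge_node_pairs(net.n_nodes)
    strength = np.zeros(net.n_nodes)
    signed = np.zeros(net.n_nodes)
    idx = np.flatnonzero(net.edge_mask)
    w = net.edge_weight[idx]
    np.add.at(strength, iu[idx], np.abs(w))
    np.add.at(strength, ju[idx], np.abs(w))
    np.add.at(signed, iu[idx], w)
    np.add.at(signed, ju[idx], w)
    df = pd.DataFrame({
        "node_id": np.arange(net.n_nodes),
        "strength": strength,
        "signed_strength": signed,
    })
    df = df.sort_values(["strength", "node_id"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def macroscale_counts(net: ContributingNetwork, atlas: pd.DataFrame) -> pd.DataFrame:
    """Symmetric region-by-region matrix of contributing-edge counts.

    Within-region edges land on the diagonal; the region order follows the
    atlas's category order (the packaged ten-region scheme by default).
    """
    region = atlas.set_index("node_id")["macroscale_region"]
    if len(region) < net.n_nodes:
        raise ValueError("atlas does not cover all nodes")
    labels = [r for r in MACROSCALE_REGIONS if r in set(region)]
    extra = [r for r in pd.unique(region) if r not in labels]
    labels = labels + sorted(extra)
    pos = {r: i for i, r in enumerate(labels)}
    node_region = region.loc[np.arange(net.n_nodes)]
    if node_region.isna().any():
        bad = int(node_region.index[node_region.isna()][0])
        raise ValueError(f"node {bad} has no macroscale_region")
    node_pos = node_region.map(pos).to_numpy()
    iu, ju = edge_node_pairs(net.n_nodes)
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    idx = np.flatnonzero(net.edge_mask)
    for a, b in zip(node_pos[iu[idx]], node_pos[ju[idx]]):
        lo, hi = min(a, b), max(a, b)
        counts[lo, hi] += 1
    counts = counts + np.triu(counts, k=1).T
    return pd.DataFrame(counts, index=labels, columns=labels)


@dataclass
class NetworkComparison:
    """Overlap between two contributing networks on the same edge space."""

    shared_mask: np.ndarray
    unique_a: np.ndarray
    unique_b: np.ndarray
    shared_count: int
    macroscale_unique_a: pd.DataFrame | None = None
    macroscale_unique_b: pd.DataFrame | None = None


def compare_networks(net_a: ContributingNetwork, net_b: ContributingNetwork,
                     atlas: pd.DataFrame | None = None) -> NetworkComparison:
    """Shared and unique edges of two contributing networks.

    The unique-to-A network (edges predicting outcome A but not outcome B)
    gets a macroscale count matrix when an atlas is supplied, and likewise
    for B.
    """
    if net_a.edge_mask.shape != net_b.edge_mask.shape:
        raise ValueError("networks live on different edge spaces")
    shared = net_a.edge_mask & net_b.edge_mask
    ua = net_a.edge_mask & ~net_b.edge_mask
    ub = net_b.edge_mask & ~net_a.edge_mask
    ma = mb = None
    if atlas is not None:
        ma = macroscale_counts(
            ContributingNetwork(ua, net_a.edge_weight, net_a.n_nodes, net_a.n_folds),
            atlas)
        mb = macroscale_counts(
            ContributingNetwork(ub, net_b.edge_weight, net_b.n_nodes, net_b.n_folds),
            atlas)
    return NetworkComparison(
        shared_mask=shared, unique_a=ua, unique_b=ub,
        shared_count=int(shared.sum()),
        macroscale_unique_a=ma, macroscale_unique_b=mb,
    )


def plot_macroscale_counts(counts: pd.DataFrame, path=None, title=None):
    """Simple heatmap of the region-pair edge-count matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(counts.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(counts.columns)), counts.columns, rotation=90)
    ax.set_yticks(range(len(counts.index)), counts.index)
    fig.colorbar(im, ax=ax, label="edge count")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
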