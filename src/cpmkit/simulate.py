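"""Synthetic datasets with known ground truth.

The generator emulates the statistical structure the CPM analysis assumes:
n subjects each with a symmetric Fisher-z connectivity profile over N nodes,
a continuous behavioral score linearly loaded on a small planted edge set
(negative coefficients emulate a negative network), confounds (age, sex,
mean framewise displacement, a one-factor negative-emotion composite) with
configurable leakage into the score and into designated edges, and optional
missingness in the questionnaire panel.

Edge noise is Gaussian on the Fisher-z scale.  A planted edge with
coefficient beta and residual sd sigma correlates with the score at
``beta / sqrt(beta**2 + sigma**2)`` in the large-sample limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import SUBSCALES, COMPOSITE_COLUMN
from .connectome import devectorize_edges, n_edges
from .io import ConnectomeDataset, MACROSCALE_REGIONS

# Ten-region grouping of the 268-node functional parcellation (node counts
# per macroscale region).
SHEN268_MACROSCALE_COUNTS = {
    "prefrontal": 46,
    "motor": 21,
    "insular": 7,
    "parietal": 27,
    "temporal": 39,
    "occipital": 25,
    "limbic": 36,
    "cerebellum": 41,
    "subcortical": 17,
    "brainstem": 9,
}

# Questionnaire-scale parameters for the emulated discovery sample:
# behavioral score (47-item internet-addiction scale) and the five
# negative-emotion subscale totals (mean, sd).
SCORE_MEAN, SCORE_SD = 101.07, 20.41
SUBSCALE_PARAMS = {
    "state_anxiety": (40.39, 9.30),
    "depression": (6.93, 6.35),
    "perceived_stress": (17.07, 4.72),
    "negative_affect": (19.57, 5.72),
    "loneliness": (41.76, 7.48),
}
# One-factor loadings of the five subscales on the negative-emotion factor.
EMOTION_LOADINGS = {
    "state_anxiety": 0.78,
    "depression": 0.636,
    "perceived_stress": 0.786,
    "negative_affect": 0.818,
    "loneliness": 0.756,
}

_FUNCTIONAL_NETWORKS = (
    "visual", "somato-motor", "dorsal-attention", "salience",
    "frontal-parietal", "default-mode", "subcortical-cerebellar", "limbic",
)


def make_atlas(n_nodes: int = 268) -> pd.DataFrame:
    """Node -> macroscale-region atlas table.

    For 268 nodes the region sizes are the ten-region grouping of the
    268-node functional parcellation; other sizes allocate nodes to regions
    proportionally (largest remainder).  Functional-network labels,
    hemispheres and MNI coordinates are synthetic placeholders — the
    parcellation itself is consumed as an input, not derived here.
    """
    total = sum(SHEN268_MACROSCALE_COUNTS.values())
    if n_nodes == total:
        counts = dict(SHEN268_MACROSCALE_COUNTS)
    else:
        raw = {r: c * n_nodes / total for r, c in SHEN268_MACROSCALE_COUNTS.items()}
        counts = {r: int(v) for r, v in raw.items()}
        leftovers = sorted(raw, key=lambda r: raw[r] - counts[r], reverse=True)
        for r in leftovers[: n_nodes - sum(counts.values())]:
            counts[r] += 1
    rows = []
    node = 0
    for region in MACROSCALE_REGIONS:
        for i in range(counts.get(region, 0)):
            rows.append({
                "node_id": node,
                "macroscale_region": region,
                "functional_network": _FUNCTIONAL_NETWORKS[node % len(_FUNCTIONAL_NETWORKS)],
                "hemisphere": "n/a" if region == "brainstem" else ("L" if i % 2 == 0 else "R"),
                # synthetic coordinates: deterministic grid, mm scale
                "mni_x": float((node % 16) * 10 - 75),
                "mni_y": float(((node // 16) % 16) * 12 - 90),
                "mni_z": float((node // 256) * 15 - 45),
            })
            node += 1
    return pd.DataFrame(rows)


@dataclass
class ConfoundEffect:
    """Leakage of one confound into the score and a designated edge set."""

    on_score: float = 0.0
    on_edges: float = 0.0
    n_edges: int = 0


@dataclass
class SyntheticSpec:
    """Generating conditions for one synthetic study sample.

    Defaults are the package's standard signal spec: 300 subjects, 60
    nodes, 12 planted negative edges at beta = -0.35 over unit edge noise
    (planted edge-score correlation about -0.33), behavioral scores on the
    discovery questionnaire's scale, and realistic confound distributions.
    ``n_nodes=268`` gives the full parcellation-scale emulation.
    """

    n_subjects: int = 300
    n_nodes: int = 60
    n_signal_edges: int = 12
    signal_beta: float = -0.35
    signal_edges: list | None = None  # explicit [(i, j, beta), ...] overrides
    noise_sd: float = 1.0
    score_mean: float = SCORE_MEAN
    score_sd: float = SCORE_SD
    confound_effects: dict = field(default_factory=dict)  # name -> ConfoundEffect
    emotion_factor_score_corr: float = 0.3
    emotion_loadings: dict = field(default_factory=lambda: dict(EMOTION_LOADINGS))
    age_mean: float = 19.94
    age_sd: float = 7.13
    male_fraction: float = 191 / 677
    fd_sigma: float = 0.35          # log-scale sd of the lognormal FD
    fd_exceedance: float = 12 / 689  # target P(mean FD > 0.3)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.fd_exceedance < 1:
            raise ValueError("fd_exceedance must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.signal_edges is not None:
            for i, j, _ in self.signal_edges:
                if not (0 <= i < j < self.n_nodes):
                    raise ValueError(
                        f"signal edge ({i}, {j}) not in the strict upper triangle")
        elif self.n_signal_edges > n_edges(self.n_nodes):
            raise ValueError(
                f"n_signal_edges={self.n_signal_edges} exceeds the "
                f"{n_edges(self.n_nodes)} available edges for n_nodes={self.n_nodes}")


@dataclass
class SyntheticDataset:
    """A generated dataset together with its generating ground truth."""

    dataset: ConnectomeDataset
    panel: pd.DataFrame                  # subscale panel (with any masked cells)
    signal_edge_idx: np.ndarray          # positions in the canonical edge order
    signal_betas: np.ndarray
    score_latent: np.ndarray             # standardized generating score
    emotion_factor: np.ndarray           # generating one-factor scores
    true_loadings: np.ndarray
    spec: SyntheticSpec


def null_spec(n_subjects: int = 100, n_nodes: int = 30, seed: int = 0,
              **kw) -> SyntheticSpec:
    """A no-signal spec (no planted edges): edges carry pure noise."""
    return SyntheticSpec(n_subjects=n_subjects, n_nodes=n_nodes,
                         n_signal_edges=0, seed=seed, **kw)


def paper_scale_spec(seed: int = 0, **kw) -> SyntheticSpec:
    """Full-scale emulation: 677 subjects, 268 nodes."""
    return SyntheticSpec(n_subjects=677, n_nodes=268, seed=seed, **kw)


def _edge_position(i, j, n_nodes):
    return (i * (2 * n_nodes - i - 1)) // 2 + (j - i - 1)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset from the generating model; deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    n, N = spec.n_subjects, spec.n_nodes
    E = n_edges(N)

    # --- confounds ---------------------------------------------------------
    age = rng.normal(spec.age_mean, spec.age_sd, n)
    sex = (rng.random(n) < spec.male_fraction).astype(float)
    if spec.fd_exceedance > 0:
        mu_fd = np.log(0.3) - spec.fd_sigma * stats.norm.isf(spec.fd_exceedance)
    else:
        mu_fd = np.log(0.12)
    mean_fd = np.exp(rng.normal(mu_fd, spec.fd_sigma, n))
    factor = rng.standard_normal(n)

    z_conf = {
        "age": (age - spec.age_mean) / spec.age_sd,
        "sex": (sex - spec.male_fraction)
        / np.sqrt(spec.male_fraction * (1 - spec.male_fraction)),
        "mean_fd": (np.log(mean_fd) - mu_fd) / spec.fd_sigma,
    }

    # --- behavioral score --------------------------------------------------
    rho_emo = spec.emotion_factor_score_corr
    loadings_sq = rho_emo**2 + sum(
        eff.on_score**2 for eff in spec.confound_effects.values())
    if loadings_sq >= 1:
        raise ValueError("confound + emotion loadings on the score exceed unit variance")
    u = rho_emo * factor + rng.standard_normal(n) * np.sqrt(1 - loadings_sq)
    for name, eff in spec.confound_effects.items():
        if eff.on_score:
            if name not in z_conf:
                raise ValueError(f"unknown confound {name!r} in confound_effects")
            u = u + eff.on_score * z_conf[name]
    score = spec.score_mean + spec.score_sd * u

    # --- edges -------------------------------------------------------------
    edges = rng.normal(0.0, spec.noise_sd, (n, E)) if spec.noise_sd > 0 \
        else np.zeros((n, E))
    if spec.signal_edges is not None:
        idx = np.array([_edge_position(i, j, N) for i, j, _ in spec.signal_edges],
                       dtype=int)
        betas = np.array([b for _, _, b in spec.signal_edges], dtype=float)
    else:
        idx = np.sort(rng.choice(E, size=spec.n_signal_edges, replace=False))
        betas = np.full(spec.n_signal_edges, spec.signal_beta)
    edges[:, idx] += np.outer(u, betas)
    taken = set(idx.tolist())
    for name, eff in spec.confound_effects.items():
        if eff.on_edges and eff.n_edges > 0:
            free = np.setdiff1d(np.arange(E), np.fromiter(taken, int, len(taken)))
            sel = rng.choice(free, size=eff.n_edges, replace=False)
            taken.update(sel.tolist())
            edges[:, sel] += eff.on_edges * z_conf[name][:, None]

    # --- emotion panel -----------------------------------------------------
    lam = np.array([spec.emotion_loadings[s] for s in SUBSCALES])
    eps = rng.standard_normal((n, len(SUBSCALES)))
    latent = factor[:, None] * lam + eps * np.sqrt(1 - lam**2)
    mu = np.array([SUBSCALE_PARAMS[s][0] for s in SUBSCALES])
    sd = np.array([SUBSCALE_PARAMS[s][1] for s in SUBSCALES])
    panel_full = pd.DataFrame(mu + sd * latent, columns=list(SUBSCALES))
    subject_ids = [f"S{i:04d}" for i in range(n)]
    panel_full.index = pd.Index(subject_ids, name="subject_id")

    # composite confound from the complete panel; masking applies only to
    # the panel artifact handed to the behavior-preprocessing stage
    Z = (panel_full - panel_full.mean()) / panel_full.std(ddof=1)
    composite = (Z * lam).sum(axis=1)
    panel = panel_full.copy()
    if spec.missing_rate > 0:
        mask = rng.random(panel.shape) < spec.missing_rate
        # keep at least one observed value per subscale
        for c in range(mask.shape[1]):
            if mask[:, c].all():
                mask[rng.integers(n), c] = False
        panel = panel.mask(mask)

    behavior = pd.DataFrame(
        {
            "score": score,
            "age": age,
            "sex": sex,
            "mean_fd": mean_fd,
            COMPOSITE_COLUMN: composite.to_numpy(),
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )
    dataset = ConnectomeDataset(
        subject_ids=subject_ids,
        edge_matrix=edges,
        n_nodes=N,
        behavior=behavior,
        target_name="score",
        confound_names=("age", "sex", "mean_fd", COMPOSITE_COLUMN),
    )
    return SyntheticDataset(
        dataset=dataset,
        panel=panel,
        signal_edge_idx=idx,
        signal_betas=betas,
        score_latent=u,
        emotion_factor=factor,
        true_loadings=lam,
        spec=spec,
    )


def generate_timeseries(target_fc: np.ndarray, n_timepoints: int,
                        seed: int = 0) -> np.ndarray:
    """Draw node time series whose population correlation matches a target.

    ``target_fc`` is a Fisher-z connectivity matrix; it is mapped back to
    correlations (unit diagonal) and must be positive definite.  Returns a
    (n_timepoints, n_nodes) array; the sample connectivity converges to the
    target as the series lengthens.
    """
    if n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    target_fc = np.asarray(target_fc, dtype=float)
    corr = np.tanh(target_fc)
    np.fill_diagonal(corr, 1.0)
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("target correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_timepoints, corr.shape[0])) @ L.T


def write_synthetic_run(sdata: SyntheticDataset, out_dir) -> None:
    """Write the on-disk layout the pipeline consumes, plus the ground truth."""
    from pathlib import Path
    import json

    from .connectome import edge_node_pairs
    from .io import write_connectivity_matrix, _jsonify

    out = Path(out_dir)
    fc_dir = out / "fc"
    fc_dir.mkdir(parents=True, exist_ok=True)
    ds = sdata.dataset
    for row, sid in zip(ds.edge_matrix, ds.subject_ids):
        write_connectivity_matrix(fc_dir / f"{sid}.tsv",
                                  devectorize_edges(row, ds.n_nodes))
    ds.behavior.reset_index().to_csv(out / "behavior.tsv", sep="\t", index=False)
    sdata.panel.reset_index().to_csv(out / "panel.tsv", sep="\t", index=False)
    make_atlas(ds.n_nodes).to_csv(out / "atlas.tsv", sep="\t", index=False)
    iu, ju = edge_node_pairs(ds.n_nodes)
    truth = {
        "seed": sdata.spec.seed,
        "signal_edges": [
            [int(iu[e]), int(ju[e]), float(b)]
            for e, b in zip(sdata.signal_edge_idx, sdata.signal_betas)
        ],
        "true_loadings": sdata.true_loadings.tolist(),
        "emotion_factor_score_corr": sdata.spec.emotion_factor_score_corr,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(_jsonify(truth), fh, indent=2, sort_keys=True)
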