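"""On-disk formats, shared dataset containers and run configuration.

Everything is plain delimited text: connectivity matrices as N x N TSV,
behavior and atlas tables as TSV with headers, edge masks as
(node_i, node_j, weight) TSV, reports as JSON.  Every edge-level artifact
declares the vectorization convention (strict upper triangle, i < j,
row-major, 0-based) in a header comment.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectome import n_edges, edge_node_pairs, validate_fc, vectorize_edges

EDGE_ORDER_NOTE = "edge order: strict upper triangle (i<j), row-major, 0-based nodes"

MACROSCALE_REGIONS = (
    "prefrontal",
    "motor",
    "insular",
    "parietal",
    "temporal",
    "occipital",
    "limbic",
    "cerebellum",
    "subcortical",
    "brainstem",
)


@dataclass
class SubjectRecord:
    """One row of the behavioral table.

    ``target_score`` or individual confounds may be missing (NaN); missing
    values are flagged, never silently dropped.
    """

    subject_id: str
    target_score: float
    confounds: dict[str, float] = field(default_factory=dict)

    @property
    def missing(self) -> list[str]:
        out = []
        if self.target_score is None or (
            isinstance(self.target_score, float) and math.isnan(self.target_score)
        ):
            out.append("target_score")
        for k, v in self.confounds.items():
            if v is None or (isinstance(v, float) and math.isnan(v)):
                out.append(k)
        return out


@dataclass
class ConnectomeDataset:
    """Subjects x edges design matrix plus behavioral records.

    ``edge_matrix`` rows follow ``subject_ids`` order; columns follow the
    canonical edge order for ``n_nodes`` nodes.
    """

    subject_ids: list[str]
    edge_matrix: np.ndarray
    n_nodes: int
    behavior: pd.DataFrame  # indexed by subject_id: target + confound columns
    target_name: str = "score"
    confound_names: tuple[str, ...] = ()

    def __post_init__(self):
        n, e = self.edge_matrix.shape
        if n != len(self.subject_ids):
            raise ValueError("edge_matrix row count != number of subjects")
        if e != n_edges(self.n_nodes):
            raise ValueError(
                f"edge_matrix has {e} columns, expected "
                f"{n_edges(self.n_nodes)} for n_nodes={self.n_nodes}"
            )
        if not np.all(np.isfinite(self.edge_matrix)):
            raise ValueError("edge_matrix contains non-finite values")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def scores(self) -> np.ndarray:
        return self.behavior.loc[self.subject_ids, self.target_name].to_numpy(float)

    def confound_matrix(self, names=None) -> np.ndarray | None:
        names = tuple(names if names is not None else self.confound_names)
        if not names:
            return None
        return self.behavior.loc[self.subject_ids, list(names)].to_numpy(float)


@dataclass
class AnalysisConfig:
    """Run configuration mirroring the CLI flags."""

    selection_p_threshold: float = 0.01
    cv_scheme: str = "loo"  # "loo" or "kfold"
    k: int = 10
    kfold_repeats: int = 100
    n_permutations: int = 1000
    perm_kfold_repeats: int = 10
    alpha: float = 0.05
    confound_names: tuple[str, ...] = ()
    rng_seed: int = 0
    fd_exclusion_threshold: float = 0.3
    normalize_edges: bool = False

    def __post_init__(self):
        if not 0 < self.selection_p_threshold < 1:
            raise ValueError("selection_p_threshold must be in (0, 1)")
        if self.cv_scheme not in ("loo", "kfold"):
            raise ValueError("cv_scheme must be 'loo' or 'kfold'")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        self.confound_names = tuple(self.confound_names)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["confound_names"] = list(self.confound_names)
        return d


# ---------------------------------------------------------------------------
# readers


def read_connectivity_matrix(path, n_nodes: int) -> np.ndarray:
    """Read one subject's N x N connectivity TSV; validate and zero diagonal."""
    try:
        mat = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in connectivity matrix") from exc
    if mat.shape != (n_nodes, n_nodes):
        raise ValueError(
            f"{path}: expected {n_nodes}x{n_nodes} matrix, got {mat.shape[0]}x{mat.shape[1]}"
        )
    try:
        return validate_fc(mat)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_timeseries(path) -> np.ndarray:
    """Read a T x N node time-series table."""
    return np.loadtxt(path, ndmin=2)


def read_behavior_table(path, target_name: str, confound_names=()) -> list[SubjectRecord]:
    """Read the behavioral TSV into SubjectRecords.

    Requires a ``subject_id`` column plus the target and confound columns;
    empty cells become NaN and are flagged missing on the record.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = ["subject_id", target_name, *confound_names]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required column(s) {missing_cols}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate subject id {dup.iloc[0]!r}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                subject_id=row["subject_id"],
                target_score=float(row[target_name]),
                confounds={c: float(row[c]) for c in confound_names},
            )
        )
    return records


def records_to_frame(records: list[SubjectRecord], target_name: str = "score") -> pd.DataFrame:
    rows = {}
    for rec in records:
        rows[rec.subject_id] = {target_name: rec.target_score, **rec.confounds}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def read_atlas(path, n_nodes: int | None = None) -> pd.DataFrame:
    """Read the node -> region atlas table.

    Columns: node_id, macroscale_region, functional_network, hemisphere,
    mni_x, mni_y, mni_z.  node_ids must be exactly 0..N-1.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("node_id", "macroscale_region"):
        if col not in df.columns:
            raise ValueError(f"{path}: atlas missing column {col!r}")
    df = df.sort_values("node_id").reset_index(drop=True)
    ids = df["node_id"].to_numpy()
    n = n_nodes if n_nodes is not None else len(df)
    if len(df) != n or not np.array_equal(ids, np.arange(n)):
        raise ValueError(f"{path}: atlas node_ids must be exactly 0..{n - 1}")
    if df["macroscale_region"].isna().any():
        bad = int(df.loc[df["macroscale_region"].isna(), "node_id"].iloc[0])
        raise ValueError(f"{path}: node {bad} has no macroscale_region")
    return df


def assemble_dataset(
    matrices: dict[str, np.ndarray],
    records: list[SubjectRecord],
    target_name: str = "score",
    confound_names=(),
) -> ConnectomeDataset:
    """Stack per-subject matrices into the subjects x edges design matrix."""
    if not records:
        raise ValueError("no subjects")
    shapes = {m.shape for m in matrices.values()}
    if len(shapes) > 1:
        raise ValueError(f"connectivity matrices with differing sizes: {sorted(shapes)}")
    missing = [r.subject_id for r in records if r.subject_id not in matrices]
    if missing:
        raise ValueError(f"no connectivity matrix for subject(s) {missing}")
    n_nodes = next(iter(matrices.values())).shape[0]
    rows = [vectorize_edges(matrices[r.subject_id]) for r in records]
    return ConnectomeDataset(
        subject_ids=[r.subject_id for r in records],
        edge_matrix=np.vstack(rows),
        n_nodes=n_nodes,
        behavior=records_to_frame(records, target_name),
        target_name=target_name,
        confound_names=tuple(confound_names),
    )


def load_run_inputs(fc_dir, behavior_path, target_name, confound_names, n_nodes=None):
    """Load a run directory: one ``<subject_id>.tsv`` matrix per subject."""
    records = read_behavior_table(behavior_path, target_name, confound_names)
    fc_dir = Path(fc_dir)
    matrices = {}
    for rec in records:
        p = fc_dir / f"{rec.subject_id}.tsv"
        if not p.exists():
            raise FileNotFoundError(f"no connectivity file for subject {rec.subject_id}: {p}")
        if n_nodes is None:
            n_nodes = np.loadtxt(p, ndmin=2).shape[0]
        matrices[rec.subject_id] = read_connectivity_matrix(p, n_nodes)
    return assemble_dataset(matrices, records, target_name, confound_names)


# ---------------------------------------------------------------------------
# writers


def write_connectivity_matrix(path, mat: np.ndarray) -> None:
    np.savetxt(path, np.asarray(mat), delimiter="\t", fmt="%.17g")


def write_edge_mask(path, mask: np.ndarray, weights: np.ndarray, n_nodes: int,
                    atlas: pd.DataFrame | None = None) -> None:
    """Write masked edges as (node_i, node_j, weight[, region_i, region_j])."""
    iu, ju = edge_node_pairs(n_nodes)
    idx = np.flatnonzero(np.asarray(mask, bool))
    cols = {
        "node_i": iu[idx],
        "node_j": ju[idx],
        "weight": np.asarray(weights, float)[idx],
    }
    if atlas is not None:
        region = atlas.set_index("node_id")["macroscale_region"]
        cols["region_i"] = region.loc[iu[idx]].to_numpy()
        cols["region_j"] = region.loc[ju[idx]].to_numpy()
    with open(path, "w") as fh:
        fh.write(f"# {EDGE_ORDER_NOTE}\n")
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_edge_mask(path, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Read an edge-mask TSV back into (bool mask, weight vector)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    e = n_edges(n_nodes)
    mask = np.zeros(e, dtype=bool)
    weights = np.zeros(e)
    i = df["node_i"].to_numpy(int)
    j = df["node_j"].to_numpy(int)
    # position of edge (i, j), i<j, in row-major upper-triangle order
    pos = (i * (2 * n_nodes - i - 1)) // 2 + (j - i - 1)
    mask[pos] = True
    weights[pos] = df["weight"].to_numpy(float)
    return mask, weights


def write_predictions(path, subject_ids, observed, predicted, fold=None) -> None:
    cols = {"subject_id": subject_ids, "observed": observed, "predicted": predicted}
    if fold is not None:
        cols["fold"] = fold
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject_id": str})


def write_report(path, report: dict) -> None:
    """Serialise the run report deterministically (sorted keys)."""
    with open(path, "w") as fh:
        json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj
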