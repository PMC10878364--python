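"""Functional-connectivity matrices and their edge-vector form.

A subject's resting-state connectome is summarised as an ``N x N`` symmetric
matrix of Fisher r-to-z transformed Pearson correlations between regional
time courses.  The strict upper triangle (``i < j``, row-major, 0-based) is
the canonical edge-vector order used throughout the package; the diagonal is
stored as 0 and never enters the edge vector.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "fisher_z",
    "inverse_fisher_z",
    "timeseries_to_fc",
    "n_edges",
    "edge_node_pairs",
    "vectorize_edges",
    "devectorize_edges",
    "validate_fc",
]

_SYMMETRY_TOL = 1e-8


def fisher_z(r):
    """Fisher r-to-z transform, ``z = atanh(r)``.

    Parameters
    ----------
    r : float or array-like
        Correlation coefficient(s), each strictly inside (-1, 1).

    Returns
    -------
    float or ndarray
        Variance-stabilised value(s); an odd function of ``r``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    """Inverse transform, ``r = tanh(z)``."""
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return float(out) if out.ndim == 0 else out


def timeseries_to_fc(ts: np.ndarray) -> np.ndarray:
    """Build a Fisher-z connectivity matrix from node time series.

    Parameters
    ----------
    ts : ndarray of shape (n_timepoints, n_nodes)
        Mean regional signal per timepoint; at least 3 timepoints, all
        values finite, every column with nonzero variance.

    Returns
    -------
    ndarray of shape (n_nodes, n_nodes)
        Symmetric matrix with ``z[i, j] = atanh(pearson(col_i, col_j))``
        off the diagonal and 0 on it.

    Raises
    ------
    ValueError
        On fewer than 3 timepoints, non-finite input, a zero-variance node,
        or a perfectly correlated node pair (infinite z).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D (timepoints x nodes) array")
    t, n = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 timepoints, got {t}")
    if not np.all(np.isfinite(ts)):
        raise ValueError("time series contains non-finite values")
    sd = ts.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance time series for node {bad[0]}")
    r = np.corrcoef(ts, rowvar=False)
    off = ~np.eye(n, dtype=bool)
    # clip fp overshoot beyond +/-1; exact +/-1 between distinct nodes is an error
    perfect = off & (np.abs(r) >= 1 - 1e-15)
    if perfect.any():
        i, j = np.argwhere(perfect)[0]
        raise ValueError(
            f"perfect correlation between distinct nodes {i} and {j}: "
            "Fisher z is infinite"
        )
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return z


def n_edges(n_nodes: int) -> int:
    """Number of unordered node pairs, ``N(N-1)/2``."""
    return n_nodes * (n_nodes - 1) // 2


def edge_node_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Node index pairs (i, j), i < j, in canonical edge order."""
    return np.triu_indices(n_nodes, k=1)


def validate_fc(mat: np.ndarray, tol: float = _SYMMETRY_TOL) -> np.ndarray:
    """Validate a square connectivity matrix; returns it with zeroed diagonal.

    Raises ``ValueError`` naming the first offending pair when the matrix is
    asymmetric beyond ``tol``, or when an off-diagonal entry is non-finite.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"connectivity matrix must be square, got shape {mat.shape}")
    asym = np.abs(mat - mat.T)
    if np.nanmax(asym, initial=0.0) > tol:
        i, j = np.argwhere(asym > tol)[0]
        raise ValueError(
            f"asymmetric connectivity matrix at ({i}, {j}): "
            f"{mat[i, j]!r} vs {mat[j, i]!r}"
        )
    out = mat.copy()
    np.fill_diagonal(out, 0.0)
    if not np.all(np.isfinite(out)):
        i, j = np.argwhere(~np.isfinite(out))[0]
        raise ValueError(f"non-finite connectivity value at ({i}, {j})")
    return out


def vectorize_edges(fc: np.ndarray) -> np.ndarray:
    """Strict-upper-triangle edge vector of a symmetric matrix.

    Order is row-major over pairs ``(i, j)`` with ``i < j``; length
    ``N(N-1)/2``.
    """
    fc = validate_fc(fc)
    iu, ju = np.triu_indices(fc.shape[0], k=1)
    return fc[iu, ju].copy()


def devectorize_edges(vec: np.ndarray, n_nodes: int) -> np.ndarray:
    """Rebuild the symmetric matrix (zero diagonal) from an edge vector."""
    vec = np.asarray(vec, dtype=float)
    expected = n_edges(n_nodes)
    if vec.shape != (expected,):
        raise ValueError(
            f"edge vector of length {vec.shape} does not match "
            f"n_nodes={n_nodes} (expected {expected})"
        )
    mat = np.zeros((n_nodes, n_nodes))
    iu, ju = np.triu_indices(n_nodes, k=1)
    mat[iu, ju] = vec
    mat[ju, iu] = vec
    return mat
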