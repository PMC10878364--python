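"""Behavioral preprocessing: motion exclusion, imputation, emotion composite.

The negative-emotion composite collapses five questionnaire totals (state
anxiety, depression, perceived stress, negative affect, loneliness) into one
score: each subscale is standardized, the first principal component of their
correlation matrix is extracted, and the composite is the loading-weighted
sum of the standard scores.  Loadings are the component's correlations with
the subscales (eigenvector scaled by the square root of the eigenvalue),
oriented so their sum is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer, SimpleImputer
from sklearn.utils.validation import check_array, check_is_fitted

SUBSCALES = (
    "state_anxiety",
    "depression",
    "perceived_stress",
    "negative_affect",
    "loneliness",
)

COMPOSITE_COLUMN = "negative_emotion"


def filter_by_motion(records, threshold: float = 0.3):
    """Exclude subjects with excessive head motion (mean FD above threshold).

    Retention is ``mean_fd <= threshold``: a subject exactly at the
    threshold is kept, matching the strict ``> threshold`` exclusion rule.

    Parameters
    ----------
    records : list of SubjectRecord
        Each must carry a ``mean_fd`` confound.
    threshold : float
        Exclusion threshold in mm (default 0.3).

    Returns
    -------
    (retained, excluded_ids) : (list of SubjectRecord, list of str)
    """
    retained, excluded = [], []
    for rec in records:
        fd = rec.confounds.get("mean_fd")
        if fd is None or (isinstance(fd, float) and np.isnan(fd)):
            raise ValueError(f"subject {rec.subject_id!r} has no mean_fd")
        if fd > threshold:
            excluded.append(rec.subject_id)
        else:
            retained.append(rec)
    return retained, excluded


def impute_missing(panel: pd.DataFrame, strategy: str = "forest", seed: int = 0) -> pd.DataFrame:
    """Complete a subjects x subscales panel.

    Strategies: ``"mean"`` (column means) and ``"forest"`` (iterative
    imputation with an extra-trees ensemble, the default for questionnaire
    totals); a fitted-transformer instance may be passed directly for any
    other scheme.  Observed cells are never modified; output is
    deterministic given ``seed``.
    """
    empty = [c for c in panel.columns if panel[c].notna().sum() == 0]
    if empty:
        raise ValueError(f"subscale(s) with zero observed values: {empty}")
    if not panel.isna().any().any():
        return panel.copy()
    if strategy == "mean":
        imputer = SimpleImputer(strategy="mean")
    elif strategy == "forest":
        imputer = IterativeImputer(
            estimator=ExtraTreesRegressor(n_estimators=30, random_state=seed),
            random_state=seed,
            max_iter=10,
            sample_posterior=False,
        )
    elif hasattr(strategy, "fit_transform"):
        imputer = strategy
    else:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    values = imputer.fit_transform(panel.to_numpy(float))
    out = pd.DataFrame(values, index=panel.index, columns=panel.columns)
    out[panel.notna()] = panel
    return out


@dataclass
class CompositeResult:
    """First-principal-component summary of the subscale panel."""

    loadings: pd.Series
    eigenvalue: float
    variance_explained: float  # percent of total subscale variance
    composite: pd.Series


class NegativeEmotionComposite(TransformerMixin, BaseEstimator):
    """First-PC composite of standardized negative-emotion subscales.

    ``fit`` standardizes each column, eigendecomposes the correlation
    matrix and stores the first-component loadings; ``transform`` returns
    the per-subject composite ``sum_i z_i * loading_i``.  Warnings are
    issued when the leading eigenvalue is <= 1 or a second eigenvalue
    exceeds 1 (a single dominant factor is the expected structure).

    Attributes
    ----------
    loadings_ : ndarray of shape (n_subscales,)
        Component correlations with each subscale, oriented so their sum
        is positive.
    eigenvalue_ : float
    variance_explained_ : float
        ``100 * eigenvalue_ / n_subscales``.
    mean_, scale_ : ndarray
        Per-subscale standardization parameters (ddof=1 sd).
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=3)
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        bad = np.flatnonzero(self.scale_ == 0)
        if bad.size:
            raise ValueError(f"zero-variance subscale at column {bad[0]}")
        Z = (X - self.mean_) / self.scale_
        corr = np.corrcoef(Z, rowvar=False)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        v = eigvec[:, 0]
        if v.sum() < 0:
            v = -v
        lam = float(eigval[0])
        self.loadings_ = v * np.sqrt(max(lam, 0.0))
        self.eigenvalue_ = lam
        self.eigenvalues_ = eigval
        self.variance_explained_ = 100.0 * lam / corr.shape[0]
        if lam <= 1:
            warnings.warn(
                f"leading eigenvalue {lam:.3f} <= 1: no dominant common factor",
                stacklevel=2,
            )
        if len(eigval) > 1 and eigval[1] > 1:
            warnings.warn(
                f"second eigenvalue {eigval[1]:.3f} > 1: more than one factor retained "
                "by the eigenvalue-1 rule",
                stacklevel=2,
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        X = check_array(X)
        Z = (X - self.mean_) / self.scale_
        return Z @ self.loadings_


def negative_emotion_composite(panel: pd.DataFrame) -> CompositeResult:
    """Functional wrapper around :class:`NegativeEmotionComposite`.

    Requires a complete panel (impute first); returns loadings, the leading
    eigenvalue, percent variance explained, and the per-subject composite.
    """
    if panel.isna().any().any():
        raise ValueError("panel has missing values; run impute_missing first")
    est = NegativeEmotionComposite().fit(panel.to_numpy(float))
    return CompositeResult(
        loadings=pd.Series(est.loadings_, index=panel.columns),
        eigenvalue=est.eigenvalue_,
        variance_explained=est.variance_explained_,
        composite=pd.Series(est.transform(panel.to_numpy(float)), index=panel.index,
                            name=COMPOSITE_COLUMN),
    )


def composite_from_loadings(panel: pd.DataFrame, loadings) -> pd.Series:
    """Loading-weighted sum of standard scores with externally given loadings."""
    Z = (panel - panel.mean()) / panel.std(ddof=1)
    return (Z * np.asarray(loadings, float)).sum(axis=1).rename(COMPOSITE_COLUMN)
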