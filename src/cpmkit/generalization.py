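"""External-sample prediction from averaged leave-one-out model parameters.

Each LOOCV iteration of the discovery sample yields one strength model
(slope, intercept, normalization parameters).  Their arithmetic means,
together with the discovery contributing-network edge mask, define a single
fixed model that is applied to every subject of an independent validation
sample; performance is the (partial) correlation between the predicted and
observed validation scores.  The correlation is scale-free, so differing
questionnaires between samples affect only the predicted-score units, not
the reported outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cpm import StrengthModel, evaluate, network_strength, predict_score


@dataclass
class AveragedModel:
    """Mean LOOCV regression and normalization parameters plus the edge mask."""

    mean_slope: float
    mean_intercept: float
    mean_strength_mean: float
    mean_strength_sd: float
    mean_score_mean: float
    mean_score_sd: float
    source_mask: np.ndarray
    n_models_averaged: int

    def as_strength_model(self) -> StrengthModel:
        return StrengthModel(
            slope=self.mean_slope,
            intercept=self.mean_intercept,
            strength_mean=self.mean_strength_mean,
            strength_sd=self.mean_strength_sd,
            score_mean=self.mean_score_mean,
            score_sd=self.mean_score_sd,
        )


def average_models(fold_models: list[StrengthModel], source_mask) -> AveragedModel:
    """Arithmetic mean of each model parameter across LOOCV folds."""
    if not fold_models:
        raise ValueError("no models to average")
    source_mask = np.asarray(source_mask, dtype=bool)
    return AveragedModel(
        mean_slope=float(np.mean([m.slope for m in fold_models])),
        mean_intercept=float(np.mean([m.intercept for m in fold_models])),
        mean_strength_mean=float(np.mean([m.strength_mean for m in fold_models])),
        mean_strength_sd=float(np.mean([m.strength_sd for m in fold_models])),
        mean_score_mean=float(np.mean([m.score_mean for m in fold_models])),
        mean_score_sd=float(np.mean([m.score_sd for m in fold_models])),
        source_mask=source_mask,
        n_models_averaged=len(fold_models),
    )


def external_predict(avg: AveragedModel, edge_matrix, scores=None, confounds=None,
                     normalize="discovery"):
    """Predict an external sample with the averaged discovery model.

    Network strengths are summed over the discovery contributing-network
    mask and, by default, normalized with the averaged discovery training
    parameters (``normalize="validation"`` re-z-scores strengths within the
    validation sample instead, useful when the two samples use differently
    scaled questionnaires).

    Returns
    -------
    predicted : ndarray
        Predicted scores on the discovery questionnaire's scale.
    r, partial_r : float or None
        Present when ``scores`` is given (requires n >= 3); partial r when
        confounds are also given.
    """
    edge_matrix = np.asarray(edge_matrix, dtype=float)
    if edge_matrix.ndim != 2 or edge_matrix.shape[1] != avg.source_mask.shape[0]:
        raise ValueError(
            f"validation edge space {edge_matrix.shape} does not match the "
            f"discovery mask length {avg.source_mask.shape[0]}")
    strengths = network_strength(edge_matrix, avg.source_mask)
    model = avg.as_strength_model()
    if normalize == "validation":
        sd = strengths.std(ddof=1) if len(strengths) > 1 else 0.0
        if sd > 0:
            model = StrengthModel(
                slope=model.slope, intercept=model.intercept,
                strength_mean=float(strengths.mean()), strength_sd=float(sd),
                score_mean=model.score_mean, score_sd=model.score_sd)
    elif normalize != "discovery":
        raise ValueError("normalize must be 'discovery' or 'validation'")
    predicted = predict_score(model, strengths)
    if scores is None:
        return predicted, None, None
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 3:
        raise ValueError("correlation undefined: need at least 3 validation subjects")
    r, partial_r = evaluate(predicted, scores, confounds)
    return predicted, r, partial_r
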