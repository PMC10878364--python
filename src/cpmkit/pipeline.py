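"""End-to-end orchestration: dataset -> CV -> inference -> network reports.

``run_pipeline`` runs the full analysis for both network signs and, when an
output directory is given, writes every artifact as plain text: per-sign
predictions, full-sample selection masks, contributing-network edge lists,
node-strength tables, macroscale count matrices, permutation null
distributions, averaged LOOCV model parameters, and a JSON report.  Given
identical inputs, config and seed the report is byte-identical across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import networks as net
from .cpm import (
    correlate_edges,
    cpm_kfold,
    cpm_loocv,
    permutation_test,
    select_edges,
    NETWORK_SIGNS,
)
from .generalization import average_models
from .io import (
    AnalysisConfig,
    ConnectomeDataset,
    write_edge_mask,
    write_predictions,
    write_report,
    _jsonify,
)


def run_pipeline(config: AnalysisConfig, dataset: ConnectomeDataset,
                 atlas: pd.DataFrame | None = None, out_dir=None) -> dict:
    """Run selection, cross-validated prediction, inference and
    network characterization; returns the report dict."""
    X = dataset.edge_matrix
    y = dataset.scores
    confounds = dataset.confound_matrix(config.confound_names)

    stage = "edge correlation"
    try:
        full_r, full_p = correlate_edges(X, y, confounds)
        selection = select_edges(full_r, full_p, config.selection_p_threshold)

        stage = "cross-validation"
        if config.cv_scheme == "loo":
            results = cpm_loocv(X, y, confounds,
                                threshold=config.selection_p_threshold,
                                normalize_edges=config.normalize_edges)
        else:
            results = cpm_kfold(X, y, confounds,
                                threshold=config.selection_p_threshold,
                                k=config.k, repeats=config.kfold_repeats,
                                seed=config.rng_seed,
                                normalize_edges=config.normalize_edges)

        stage = "permutation test"
        perms = None
        if config.n_permutations > 0:
            observed = {
                s: (results[s].performance_r if confounds is None
                    else results[s].performance_partial_r)
                for s in NETWORK_SIGNS
            }
            perms = permutation_test(
                X, y, observed, confounds,
                threshold=config.selection_p_threshold,
                scheme=config.cv_scheme, k=config.k,
                kfold_repeats=config.perm_kfold_repeats,
                n_permutations=config.n_permutations,
                seed=config.rng_seed,
                normalize_edges=config.normalize_edges)

        stage = "contributing network"
        contrib = {}
        for s in NETWORK_SIGNS:
            if results[s].fold_masks is not None:
                contrib[s] = net.contributing_network(
                    results[s].fold_masks, full_r, dataset.n_nodes)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    report = {
        "config": config.to_dict(),
        "seed": config.rng_seed,
        "n_subjects": dataset.n_subjects,
        "n_nodes": dataset.n_nodes,
        "n_edges": X.shape[1],
        "target": dataset.target_name,
        "networks": {},
    }
    for s in NETWORK_SIGNS:
        cv = results[s]
        entry = {
            "performance_r": cv.performance_r,
            "performance_partial_r": cv.performance_partial_r,
            "fold_mask_size_min": int(min(cv.fold_mask_sizes)),
            "fold_mask_size_max": int(max(cv.fold_mask_sizes)),
            "n_degenerate_folds": cv.n_degenerate_folds,
            "full_sample_selected": int(selection.mask(s).sum()),
            "permutation_p": None,
            "permutation_p_raw": None,
        }
        if cv.per_repeat_r is not None:
            entry["per_repeat_r_mean"] = float(np.mean(cv.per_repeat_r))
            entry["per_repeat_r"] = [float(v) for v in cv.per_repeat_r]
        if perms is not None:
            entry["permutation_p"] = perms[s].p_value
            entry["permutation_p_raw"] = perms[s].p_value_raw
        if s in contrib:
            entry["contributing_edges"] = contrib[s].n_edges_selected
        report["networks"][s] = entry

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_edge_mask(out / "selection_positive.tsv", selection.pos_mask,
                        full_r, dataset.n_nodes, atlas)
        write_edge_mask(out / "selection_negative.tsv", selection.neg_mask,
                        full_r, dataset.n_nodes, atlas)
        for s in NETWORK_SIGNS:
            cv = results[s]
            fold = None
            if cv.scheme == "loo":
                fold = np.arange(dataset.n_subjects)
            write_predictions(out / f"predictions_{s}.tsv", dataset.subject_ids,
                              cv.observed, cv.predicted, fold)
            if perms is not None:
                pd.DataFrame({"r_perm": perms[s].null_distribution}).to_csv(
                    out / f"null_{s}.tsv", sep="\t", index=False,
                    float_format="%.17g")
            if s in contrib:
                cn = contrib[s]
                write_edge_mask(out / f"contributing_{s}.tsv", cn.edge_mask,
                                cn.edge_weight, dataset.n_nodes, atlas)
                ns = net.node_strength(cn)
                if atlas is not None:
                    ns = ns.merge(atlas, on="node_id", how="left")
                ns.to_csv(out / f"node_strength_{s}.tsv", sep="\t", index=False,
                          float_format="%.17g")
                if atlas is not None:
                    net.macroscale_counts(cn, atlas).to_csv(
                        out / f"macroscale_counts_{s}.tsv", sep="\t")
            if cv.scheme == "loo" and cv.fold_models is not None and s in contrib:
                avg = average_models(cv.fold_models, contrib[s].edge_mask)
                params = {
                    "mean_slope": avg.mean_slope,
                    "mean_intercept": avg.mean_intercept,
                    "mean_strength_mean": avg.mean_strength_mean,
                    "mean_strength_sd": avg.mean_strength_sd,
                    "mean_score_mean": avg.mean_score_mean,
                    "mean_score_sd": avg.mean_score_sd,
                    "n_models_averaged": avg.n_models_averaged,
                    "n_nodes": dataset.n_nodes,
                }
                with open(out / f"averaged_model_{s}.json", "w") as fh:
                    json.dump(_jsonify(params), fh, indent=2, sort_keys=True)
        write_report(out / "report.json", report)
    return report
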