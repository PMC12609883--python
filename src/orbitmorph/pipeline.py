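"""End-to-end seeded run: simulate/read -> derive -> classify -> test.

``run_full_pipeline`` wires the modules together and emits one report
dictionary (schema: :mod:`orbitmorph.report`).  Every stage failure is
re-raised as :class:`StageError` naming the stage, so a caller can map
stages to exit codes.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .classifier import CutoffSet, classify_depth_only_frame, classify_full_frame, evaluate
from .derivation import (
    cv_lda,
    derive_rule_cutoffs,
    kmeans,
    name_clusters,
    optimize_depth_cutoffs,
    standardize,
)
from .morphometry import DIMENSION_COLUMNS, read_measurements
from .report import validate_report
from .stats import anova_eta2, kruskal_wallis
from .synthetic_data import DIMENSIONS, empirical_summary, generate_cohort

logger = logging.getLogger("orbitmorph")

#: column order expected by the derivation helpers: (depth, height, width)
_RAW_COLUMNS = list(DIMENSION_COLUMNS)

SMALL_SAMPLE_N = 60  # below this, CV folds and bootstrap CIs are unstable


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunConfig(BaseModel):
    """Configuration of one pipeline run."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n: int = Field(default=499, ge=1)
    input_path: Optional[Path] = None  # None -> simulate
    cutoffs: CutoffSet = CutoffSet()
    bootstrap_B: int = Field(default=1000, ge=1)
    folds: int = Field(default=5, ge=2)
    kmeans_restarts: int = Field(default=10, ge=1)


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the whole analysis and return a schema-valid report dict."""
    notes: list = []

    try:
        if config.input_path is not None:
            frame = read_measurements(config.input_path)
            source = str(config.input_path)
        else:
            frame = generate_cohort(n=config.n, seed=config.seed).data
            source = "simulated"
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("input", e) from e
    n = len(frame)
    if n < SMALL_SAMPLE_N:
        notes.append(
            f"small sample (n={n} < {SMALL_SAMPLE_N}): cross-validation and "
            "bootstrap estimates will be unstable"
        )
        logger.warning(notes[-1])

    have_truth = frame["true_type"].notna().all() if "true_type" in frame else False

    try:
        summary = empirical_summary(frame) if have_truth else None
    except Exception as e:
        raise StageError("descriptives", e) from e

    try:
        X_raw = frame[_RAW_COLUMNS].to_numpy(float)
        Z, scaler = standardize(X_raw)
        model = kmeans(
            Z, k=3, seed=config.seed, restarts=config.kmeans_restarts, standardizer=scaler
        )
        cluster_map = name_clusters(model, X_raw)
        km_labels = np.array([cluster_map[int(c)] for c in model.labels])
        cv_mean, cv_sd = cv_lda(Z, km_labels, folds=config.folds, seed=config.seed)
        tree = derive_rule_cutoffs(X_raw, km_labels)
        depth = optimize_depth_cutoffs(
            X_raw[:, 0], km_labels, bootstrap_B=config.bootstrap_B, seed=config.seed
        )
    except Exception as e:
        raise StageError("derivation", e) from e

    try:
        full = classify_full_frame(frame, config.cutoffs)
        donly = classify_depth_only_frame(frame, config.cutoffs)
        classification = {
            "full_vs_kmeans": evaluate(
                full["pred_type"], km_labels, bootstrap=200, seed=config.seed
            ).to_dict(),
            "depth_only_vs_kmeans": evaluate(
                donly["pred_type"], km_labels, bootstrap=200, seed=config.seed
            ).to_dict(),
        }
        if have_truth:
            truth = frame["true_type"].to_numpy(object)
            classification["full_vs_true"] = evaluate(
                full["pred_type"], truth, bootstrap=200, seed=config.seed
            ).to_dict()
            classification["depth_only_vs_true"] = evaluate(
                donly["pred_type"], truth, bootstrap=200, seed=config.seed
            ).to_dict()
    except Exception as e:
        raise StageError("classification", e) from e

    try:
        group_col = frame["true_type"] if have_truth else pd.Series(km_labels)
        tests = []
        for dim, col in zip(DIMENSIONS, _RAW_COLUMNS):
            groups = [
                frame.loc[np.asarray(group_col) == t, col].to_numpy(float)
                for t in ("A", "B", "C")
            ]
            a = anova_eta2(groups, labels=("A", "B", "C"))
            kw = kruskal_wallis(groups, labels=("A", "B", "C"))
            tests.append(
                {
                    "dimension": dim,
                    "anova_f": a.statistic,
                    "anova_df": a.df,
                    "anova_p": a.p_value,
                    "eta_squared": a.effect_size,
                    "kruskal_h": kw.statistic,
                    "kruskal_p": kw.p_value,
                }
            )
    except Exception as e:
        raise StageError("stats", e) from e

    labels_for_dist = (
        frame["true_type"].to_numpy(object) if have_truth else km_labels
    )
    values, counts = np.unique(labels_for_dist, return_counts=True)
    type_distribution = [
        {"type": str(t), "count": int(c), "prevalence": float(c) / n}
        for t, c in zip(values, counts)
    ]

    descriptives = []
    if summary is not None:
        for (t, dim), row in summary.iterrows():
            descriptives.append(
                {
                    "type": str(t),
                    "dimension": str(dim),
                    "mean": float(row["mean"]),
                    "sd": float(row["sd"]),
                    "min": float(row["min"]),
                    "max": float(row["max"]),
                    "n": int(row["n"]),
                }
            )

    report = {
        "meta": {
            "seed": config.seed,
            "n": n,
            "package_version": __version__,
            "source": source,
        },
        "type_distribution": type_distribution,
        "descriptives": descriptives,
        "group_tests": tests,
        "derivation": {
            "standardization_means": scaler.means.tolist(),
            "standardization_sds": scaler.sds.tolist(),
            "centroids_standardized": model.centers.tolist(),
            "centroids_raw": scaler.inverse(model.centers).tolist(),
            "cluster_to_type": {str(k): v for k, v in cluster_map.items()},
            "cv_accuracy_mean": cv_mean,
            "cv_accuracy_sd": cv_sd,
            "h_cut": tree.h_cut,
            "d_cut": tree.d_cut,
            "tree_accuracy": tree.tree_accuracy,
            "d1": depth.d1,
            "d2": depth.d2,
            "d1_ci": depth.d1_ci,
            "d2_ci": depth.d2_ci,
            "depth_accuracy": depth.depth_accuracy,
        },
        "classification": classification,
        "warnings": notes,
    }
    validate_report(report)
    return report
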