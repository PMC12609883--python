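"""Published threshold decision rules for the three orbital morphotypes.

Full rule (height first, then depth):

* ``H > 34.35 mm``                      -> type A (Tall & Broad)
* ``H <= 34.35 mm and D > 41.65 mm``    -> type B (Deep & Broad)
* ``H <= 34.35 mm and D <= 41.65 mm``   -> type C (Compact)

Boundary points use ``<=`` and therefore fall to C, matching the strict
``>`` in the A and B conditions.  Width never decides the label; near a
threshold it is reported as a non-overriding consistency annotation
(W above 36.25 mm leans B, W at or below 34.45 mm leans C).

Depth-only fallback, for trauma cases where height and width cannot be
measured: ``D <= d1`` -> C, ``d1 < D <= d2`` -> A, ``D > d2`` -> B with
``d1 = 40.75``, ``d2 = 41.95`` mm.  Intervals map to types by ascending
per-type mean depth (C 38.56 < A 40.1 < B 43.52 mm), which also explains
why B and C are recovered more reliably than A: A occupies the narrow
middle band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "MORPHOTYPES",
    "CutoffSet",
    "FullRuleResult",
    "MetricsReport",
    "classify_full",
    "classify_full_frame",
    "classify_depth_only",
    "classify_depth_only_frame",
    "evaluate",
]

MORPHOTYPES = ("A", "B", "C")


class CutoffSet(BaseModel):
    """The published cut-offs (mm) for the full and depth-only rules."""

    model_config = ConfigDict(frozen=True)

    h_cut: float = Field(default=34.35, gt=0)
    d_cut: float = Field(default=41.65, gt=0)
    w_support_b: float = Field(default=34.45, gt=0)
    w_support_c: float = Field(default=36.25, gt=0)
    d1: float = Field(default=40.75, gt=0)
    d2: float = Field(default=41.95, gt=0)

    @model_validator(mode="after")
    def _check_order(self) -> "CutoffSet":
        if not self.d1 < self.d2:
            raise ValueError(f"d1 must be below d2, got d1={self.d1}, d2={self.d2}")
        return self


@dataclass(frozen=True)
class FullRuleResult:
    """Label plus borderline annotation from the full three-dimension rule."""

    label: str
    borderline: bool
    width_lean: Optional[str]  # "B", "C" or None; annotation only


def classify_full(
    depth_mm: float,
    height_mm: float,
    width_mm: float,
    cuts: Optional[CutoffSet] = None,
    *,
    borderline_margin: float = 0.5,
) -> FullRuleResult:
    """Apply the full height-then-depth rule to one orbit.

    The rule partitions the positive octant, so exactly one label comes
    back for any input.  When height or depth lies within
    ``borderline_margin`` mm of its threshold the result is flagged
    borderline and the width support is reported as a lean; the lean
    never overrides the primary label.
    """
    for name, v in (("depth", depth_mm), ("height", height_mm), ("width", width_mm)):
        if v is None or not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {v!r}")
    cuts = cuts or CutoffSet()
    if height_mm > cuts.h_cut:
        label = "A"
    elif depth_mm > cuts.d_cut:
        label = "B"
    else:
        label = "C"
    borderline = (
        abs(height_mm - cuts.h_cut) < borderline_margin
        or abs(depth_mm - cuts.d_cut) < borderline_margin
    )
    width_lean: Optional[str] = None
    if borderline:
        if width_mm > cuts.w_support_c:
            width_lean = "B"
        elif width_mm <= cuts.w_support_b:
            width_lean = "C"
    return FullRuleResult(label=label, borderline=borderline, width_lean=width_lean)


def classify_full_frame(
    frame: pd.DataFrame,
    cuts: Optional[CutoffSet] = None,
    *,
    borderline_margin: float = 0.5,
) -> pd.DataFrame:
    """Vectorized full rule over a measurement table.

    Returns a copy with ``pred_type``, ``borderline`` and ``width_lean``
    columns appended.
    """
    cuts = cuts or CutoffSet()
    D = frame["depth_mm"].to_numpy(float)
    H = frame["height_mm"].to_numpy(float)
    W = frame["width_mm"].to_numpy(float)
    if np.any(~np.isfinite(D) | ~np.isfinite(H) | ~np.isfinite(W)):
        raise ValueError("missing or non-finite dimension values")
    if np.any(D <= 0) or np.any(H <= 0) or np.any(W <= 0):
        raise ValueError("dimensions must be strictly positive")
    label = np.where(H > cuts.h_cut, "A", np.where(D > cuts.d_cut, "B", "C"))
    borderline = (np.abs(H - cuts.h_cut) < borderline_margin) | (
        np.abs(D - cuts.d_cut) < borderline_margin
    )
    lean = np.where(W > cuts.w_support_c, "B", np.where(W <= cuts.w_support_b, "C", ""))
    lean = np.where(borderline, lean, "")
    out = frame.copy()
    out["pred_type"] = label
    out["borderline"] = borderline
    out["width_lean"] = pd.Series(lean, index=out.index).replace("", None)
    return out


def classify_depth_only(depth_mm: float, cuts: Optional[CutoffSet] = None) -> str:
    """Assign a morphotype from depth alone via the two published cut-offs."""
    if depth_mm is None or not np.isfinite(depth_mm) or depth_mm <= 0:
        raise ValueError(f"depth must be a positive finite number, got {depth_mm!r}")
    cuts = cuts or CutoffSet()
    if depth_mm <= cuts.d1:
        return "C"
    if depth_mm <= cuts.d2:
        return "A"
    return "B"


def classify_depth_only_frame(
    frame: pd.DataFrame, cuts: Optional[CutoffSet] = None
) -> pd.DataFrame:
    """Vectorized depth-only rule; appends a ``pred_type`` column."""
    cuts = cuts or CutoffSet()
    D = frame["depth_mm"].to_numpy(float)
    if np.any(~np.isfinite(D)) or np.any(D <= 0):
        raise ValueError("depth must be strictly positive and finite")
    out = frame.copy()
    out["pred_type"] = np.where(D <= cuts.d1, "C", np.where(D <= cuts.d2, "A", "B"))
    return out


@dataclass(frozen=True)
class MetricsReport:
    """Confusion matrix (rows = truth A/B/C, columns = prediction) + scores."""

    confusion: np.ndarray
    labels: tuple
    accuracy: float
    precision: dict
    recall: dict
    n: int
    accuracy_ci: Optional[tuple] = None
    empty_prediction_columns: tuple = ()

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": dict(self.precision),
            "recall": dict(self.recall),
            "n": self.n,
            "ci": list(self.accuracy_ci) if self.accuracy_ci else None,
        }


def evaluate(
    predictions: Sequence[str],
    truths: Sequence[str],
    *,
    labels: Sequence[str] = MORPHOTYPES,
    bootstrap: int = 0,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MetricsReport:
    """Score predicted labels against reference labels.

    Precision for a label with an empty prediction column is reported as
    0.0 and the label is listed in ``empty_prediction_columns``.  With
    ``bootstrap > 0`` a seeded percentile bootstrap over record indices
    gives a confidence interval for the accuracy.
    """
    pred = np.asarray(predictions, dtype=object)
    true = np.asarray(truths, dtype=object)
    if pred.shape != true.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("predictions and truths must be equal-length, non-empty 1-D")
    labels = tuple(labels)
    bad = set(pred) | set(true)
    bad -= set(labels)
    if bad:
        raise ValueError(f"unknown label(s): {sorted(bad)}; expected {labels}")

    M = _sk_confusion(true, pred, labels=list(labels))
    n = int(M.sum())
    accuracy = float(np.trace(M)) / n
    col_sums = M.sum(axis=0)
    row_sums = M.sum(axis=1)
    precision = {
        lab: (float(M[k, k]) / col_sums[k] if col_sums[k] else 0.0)
        for k, lab in enumerate(labels)
    }
    recall = {
        lab: (float(M[k, k]) / row_sums[k] if row_sums[k] else 0.0)
        for k, lab in enumerate(labels)
    }
    empty = tuple(lab for k, lab in enumerate(labels) if col_sums[k] == 0)

    ci = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        hits = (pred == true).astype(float)
        accs = np.array(
            [hits[rng.integers(0, n, size=n)].mean() for _ in range(bootstrap)]
        )
        alpha = (1.0 - ci_level) / 2.0
        ci = (
            float(np.quantile(accs, alpha)),
            float(np.quantile(accs, 1.0 - alpha)),
        )
    return MetricsReport(
        confusion=M,
        labels=labels,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        n=n,
        accuracy_ci=ci,
        empty_prediction_columns=empty,
    )
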