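"""Morphotype derivation: k-means, LDA validation, and cut-off extraction.

This module re-derives the three-type classification from raw
measurements the way it was originally built:

1. z-standardize depth, height, width;
2. k-means with k = 3 (Lloyd's algorithm, k-means++ seeding, best of
   several restarts by within-cluster sum of squares);
3. name the clusters anatomically — greatest mean raw height -> A
   (Tall & Broad), then greatest mean raw depth -> B (Deep & Broad),
   remainder -> C (Compact);
4. validate separability with linear discriminant analysis under
   stratified 5-fold cross-validation;
5. distill the clusters into a constrained two-level threshold rule
   (height splits A from {B, C}, depth splits B from C) and into a
   depth-only two-cut-off rule with percentile-bootstrap confidence
   intervals.

The k-means and LDA steps are written out explicitly (Lloyd iterations
with a monotonicity assertion on the objective; the linear discriminant
score ``delta_k(x) = x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + log pi_k``)
so every numerical choice of the derivation is visible and testable
against library implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "Standardizer",
    "ClusterModel",
    "DiscriminantModel",
    "DerivedCutoffs",
    "standardize",
    "kmeans",
    "name_clusters",
    "fit_lda",
    "predict_lda",
    "cv_lda",
    "derive_rule_cutoffs",
    "optimize_depth_cutoffs",
]


# ---------------------------------------------------------------- standardize


@dataclass(frozen=True)
class Standardizer:
    """Per-column centring and scaling constants (sd with denominator n-1)."""

    means: np.ndarray
    sds: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.means) / self.sds

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, float) * self.sds + self.means


def standardize(X: np.ndarray) -> Tuple[np.ndarray, Standardizer]:
    """Column-standardize X to mean 0, sd 1 (ddof = 1); keep the constants."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        cols = np.flatnonzero(sds <= 0).tolist()
        raise ValueError(f"constant column(s) {cols}: cannot standardize")
    scaler = Standardizer(means=means, sds=sds)
    return scaler.transform(X), scaler


# -------------------------------------------------------------------- k-means


@dataclass(frozen=True)
class ClusterModel:
    """A fitted k-means partition in standardized space."""

    centers: np.ndarray  # (k, p), standardized space
    labels: np.ndarray  # (n,), cluster index of each record
    inertia: float  # within-cluster sum of squares
    standardizer: Optional[Standardizer] = None
    n_iter: int = 0


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centers with D^2 weighting."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers[j] = X[rng.integers(n)]
            continue
        centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))
    return centers


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int
) -> Tuple[np.ndarray, np.ndarray, float, int]:
    n, _ = X.shape
    k = centers.shape[0]
    prev_obj = np.inf
    labels = np.zeros(n, dtype=int)
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        obj = d2[np.arange(n), new_labels].sum()
        # Lloyd's objective never increases; a violation means a bug.
        assert obj <= prev_obj + 1e-9 * max(1.0, abs(prev_obj)), (
            f"k-means objective increased: {prev_obj} -> {obj}"
        )
        converged = it > 1 and np.array_equal(new_labels, labels)
        labels = new_labels
        prev_obj = obj
        if converged:
            break
        for j in range(k):
            members = X[labels == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:
                # re-seed an emptied cluster at the point farthest from
                # its current centroid
                far = d2[np.arange(n), labels].argmax()
                centers[j] = X[far]
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    obj = d2[np.arange(n), labels].sum()
    return centers, labels, float(obj), it


def kmeans(
    X: np.ndarray,
    k: int = 3,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 300,
    standardizer: Optional[Standardizer] = None,
) -> ClusterModel:
    """Lloyd's k-means, best of *restarts* k-means++-seeded runs.

    Deterministic for a fixed seed.  An emptied cluster is re-seeded at
    the point farthest from its assigned centroid.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    if restarts < 1 or max_iter < 1:
        raise ValueError("restarts and max_iter must be positive")
    rng = np.random.default_rng(seed)
    best: Optional[Tuple[np.ndarray, np.ndarray, float, int]] = None
    for _ in range(restarts):
        centers0 = _kmeanspp_init(X, k, rng)
        result = _lloyd(X, centers0.copy(), max_iter)
        if best is None or result[2] < best[2]:
            best = result
    centers, labels, inertia, n_iter = best
    return ClusterModel(
        centers=centers,
        labels=labels,
        inertia=inertia,
        standardizer=standardizer,
        n_iter=n_iter,
    )


def name_clusters(model: ClusterModel, X_raw: np.ndarray) -> dict:
    """Map cluster indices to morphotype letters by anatomy.

    Columns of ``X_raw`` are (depth, height, width) in mm.  The cluster
    with the greatest mean raw height is A; of the remaining two, the
    deeper is B; the last is C.  Exact ties are degenerate — a warning is
    emitted and ties break toward the lower cluster index.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    ids = np.unique(model.labels)
    if len(ids) != 3:
        raise ValueError(f"cluster naming requires exactly 3 clusters, got {len(ids)}")
    mean_h = {int(j): X_raw[model.labels == j, 1].mean() for j in ids}
    mean_d = {int(j): X_raw[model.labels == j, 0].mean() for j in ids}
    hs = sorted(mean_h.values())
    ds_all = sorted(mean_d.values())
    if hs[-1] == hs[-2] or ds_all[0] == ds_all[1] or ds_all[1] == ds_all[2]:
        warnings.warn(
            "tied cluster means during naming; breaking ties by cluster index",
            stacklevel=2,
        )
    # max() on (value, -index) keeps the lower index on exact ties
    a = max(mean_h, key=lambda j: (mean_h[j], -j))
    rest = [j for j in map(int, ids) if j != a]
    b = max(rest, key=lambda j: (mean_d[j], -j))
    c = next(j for j in rest if j != b)
    return {a: "A", b: "B", c: "C"}


# ------------------------------------------------------------------------ LDA


@dataclass(frozen=True)
class DiscriminantModel:
    """Gaussian linear discriminant: class means, pooled covariance, priors."""

    classes: tuple
    means: np.ndarray  # (k, p)
    pooled_cov: np.ndarray  # (p, p)
    priors: np.ndarray  # (k,)
    coef: np.ndarray = field(default=None)  # (k, p): Sigma^-1 mu_k
    intercept: np.ndarray = field(default=None)  # (k,)
    condition_number: float = 0.0


def fit_lda(
    X: np.ndarray,
    labels: Sequence,
    priors: Optional[np.ndarray] = None,
    max_condition: float = 1e10,
) -> DiscriminantModel:
    """Fit a linear discriminant model (shared within-class covariance).

    Priors default to the observed class proportions.  The pooled
    covariance uses the within-class sum of squares divided by (n - k);
    a condition number above ``max_condition`` is rejected as singular.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(np.unique(labels).tolist())
    k, p = len(classes), X.shape[1]
    if k < 2:
        raise ValueError("need at least 2 classes")
    counts = np.array([(labels == c).sum() for c in classes])
    if np.any(counts < 2):
        small = [c for c, m in zip(classes, counts) if m < 2]
        raise ValueError(f"each class needs >= 2 records; too small: {small}")
    means = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    sw = np.zeros((p, p))
    for i, c in enumerate(classes):
        R = X[labels == c] - means[i]
        sw += R.T @ R
    pooled = sw / (len(X) - k)
    pooled = (pooled + pooled.T) / 2.0  # symmetrize against round-off
    cond = float(np.linalg.cond(pooled))
    if not np.isfinite(cond) or cond > max_condition:
        raise ValueError(
            f"pooled covariance is numerically singular (condition number {cond:.3g})"
        )
    if priors is None:
        priors = counts / counts.sum()
    priors = np.asarray(priors, dtype=float)
    if abs(priors.sum() - 1.0) > 1e-9 or np.any(priors <= 0):
        raise ValueError("priors must be positive and sum to 1")
    inv = np.linalg.inv(pooled)
    coef = means @ inv  # row k is Sigma^-1 mu_k (transposed form)
    intercept = -0.5 * np.einsum("ij,ij->i", coef, means) + np.log(priors)
    return DiscriminantModel(
        classes=classes,
        means=means,
        pooled_cov=pooled,
        priors=priors,
        coef=coef,
        intercept=intercept,
        condition_number=cond,
    )


def lda_scores(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Linear discriminant scores delta_k(x) for each record and class."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X @ model.coef.T + model.intercept


def predict_lda(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Assign each record to the class with the highest discriminant score."""
    scores = lda_scores(model, X)
    idx = scores.argmax(axis=1)
    return np.asarray(model.classes, dtype=object)[idx]


def cv_lda(
    X: np.ndarray,
    labels: Sequence,
    folds: int = 5,
    seed: int = 0,
    priors: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Stratified k-fold cross-validated accuracy of the linear discriminant.

    Returns (mean, sd) of the per-fold accuracies; sd uses ddof = 1.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, labels):
        model = fit_lda(X[train], labels[train], priors=priors)
        pred = predict_lda(model, X[test])
        accs.append(float((pred == labels[test]).mean()))
    accs = np.asarray(accs)
    return float(accs.mean()), float(accs.std(ddof=1))


# ------------------------------------------------------------ cut-off search


@dataclass(frozen=True)
class DerivedCutoffs:
    """Thresholds distilled from labelled measurements."""

    h_cut: Optional[float] = None
    d_cut: Optional[float] = None
    tree_accuracy: Optional[float] = None
    d1: Optional[float] = None
    d2: Optional[float] = None
    d1_ci: Optional[tuple] = None
    d2_ci: Optional[tuple] = None
    depth_accuracy: Optional[float] = None


def _midpoints(values: np.ndarray) -> np.ndarray:
    u = np.unique(values)
    if len(u) < 2:
        raise ValueError("need at least 2 distinct values to place a threshold")
    return (u[:-1] + u[1:]) / 2.0


def _best_threshold(values: np.ndarray, is_upper: np.ndarray) -> float:
    """Threshold t maximizing accuracy of 'upper iff value > t'.

    Candidates are midpoints of consecutive sorted unique values; ties in
    accuracy break toward the smaller threshold.
    """
    cands = _midpoints(values)
    # correct = (# upper with value > t) + (# lower with value <= t)
    correct = np.array(
        [(is_upper & (values > t)).sum() + (~is_upper & (values <= t)).sum() for t in cands]
    )
    return float(cands[int(np.argmax(correct))])  # argmax keeps first (smallest) tie


def derive_rule_cutoffs(
    X_raw: np.ndarray, labels: Sequence, cluster_map: Optional[dict] = None
) -> DerivedCutoffs:
    """Distill labelled measurements into the two-threshold rule.

    The stump structure is constrained to the published form: the root
    threshold on height separates A from {B, C}; the child threshold on
    depth separates B from C among records at or below the root.  Each
    threshold is an exhaustive-search midpoint maximizing the accuracy of
    its own split (an unconstrained decision tree could choose different
    variables; this derivation deliberately fixes them).

    ``X_raw`` columns are (depth, height, width) in mm; *labels* are
    morphotype letters, or cluster indices together with *cluster_map*.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    labels = np.asarray(labels)
    if cluster_map is not None:
        labels = np.asarray([cluster_map[int(c)] for c in labels])
    present = set(labels.tolist())
    if present != {"A", "B", "C"}:
        raise ValueError(f"all three morphotypes must be present, got {sorted(present)}")
    D, H = X_raw[:, 0], X_raw[:, 1]
    h_cut = _best_threshold(H, labels == "A")
    below = H <= h_cut
    if len(np.unique(D[below])) < 2 or not (labels[below] == "B").any():
        raise ValueError("cannot place the depth threshold: no B/C contrast below h_cut")
    d_cut = _best_threshold(D[below], labels[below] == "B")
    pred = np.where(H > h_cut, "A", np.where(D > d_cut, "B", "C"))
    return DerivedCutoffs(
        h_cut=h_cut,
        d_cut=d_cut,
        tree_accuracy=float((pred == labels).mean()),
    )


def _depth_pair_search(D: np.ndarray, labels: np.ndarray) -> Tuple[float, float, float]:
    """Best (d1, d2) for the C/A/B interval rule, maximizing accuracy.

    With records sorted by depth and per-class cumulative counts, the
    accuracy of the cut pair (t_i, t_j), i < j, decomposes into f(i) +
    g(j) + const, so a prefix-maximum scan finds the optimum in O(n log n).
    Accuracy ties break toward the smaller (d1, d2).
    """
    order = np.argsort(D, kind="stable")
    Ds, Ls = D[order], labels[order]
    cands = _midpoints(Ds)
    # position[i] = number of depths <= cands[i]
    pos = np.searchsorted(Ds, cands, side="right")
    cum = {c: np.concatenate([[0], np.cumsum(Ls == c)]) for c in "ABC"}
    f = cum["C"][pos] - cum["A"][pos]  # contribution of the lower cut at index i
    g = cum["A"][pos] - cum["B"][pos]  # contribution of the upper cut at index j
    const = cum["B"][-1]
    # maximize f(i) + g(j) over i < j; scan j, keeping the best f so far
    best_f = np.empty(len(f))
    best_i = np.empty(len(f), dtype=int)
    running, run_i = -np.inf, -1
    for i in range(len(f)):
        best_f[i], best_i[i] = running, run_i
        if f[i] > running:  # strict: ties keep the earlier (smaller) i
            running, run_i = f[i], i
    totals = best_f[1:] + g[1:]
    j = 1 + int(np.argmax(totals))
    i = int(best_i[j])
    acc = (totals[j - 1] + const) / len(D)
    return float(cands[i]), float(cands[j]), float(acc)


def optimize_depth_cutoffs(
    depths: np.ndarray,
    labels: Sequence,
    bootstrap_B: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> DerivedCutoffs:
    """Optimize the two depth-only cut-offs and bootstrap their CIs.

    Exhaustive search over ordered midpoint pairs (d1 < d2) maximizing
    the accuracy of the C / A / B interval mapping; a seeded percentile
    bootstrap over record resamples yields confidence intervals for both
    cut-offs.
    """
    D = np.asarray(depths, dtype=float)
    labels = np.asarray(labels)
    if D.shape != labels.shape:
        raise ValueError("depths and labels must have equal length")
    present = set(labels.tolist())
    if present != {"A", "B", "C"}:
        raise ValueError(f"all three morphotypes must be present, got {sorted(present)}")
    if len(np.unique(D)) < 3:
        raise ValueError("fewer than 3 distinct depth values")
    if bootstrap_B < 1:
        raise ValueError("bootstrap_B must be >= 1")
    d1, d2, acc = _depth_pair_search(D, labels)

    rng = np.random.default_rng(seed)
    n = len(D)
    boots = np.empty((bootstrap_B, 2))
    for b in range(bootstrap_B):
        idx = rng.integers(0, n, size=n)
        Db, Lb = D[idx], labels[idx]
        if len(np.unique(Db)) < 3 or set(Lb.tolist()) != {"A", "B", "C"}:
            boots[b] = (d1, d2)  # degenerate resample: fall back to point estimate
            continue
        boots[b, 0], boots[b, 1], _ = _depth_pair_search(Db, Lb)
    alpha = (1.0 - ci_level) / 2.0
    lo1, hi1 = np.quantile(boots[:, 0], [alpha, 1 - alpha])
    lo2, hi2 = np.quantile(boots[:, 1], [alpha, 1 - alpha])
    return DerivedCutoffs(
        d1=d1,
        d2=d2,
        d1_ci=(min(float(lo1), d1), max(float(hi1), d1)),
        d2_ci=(min(float(lo2), d2), max(float(hi2), d2)),
        depth_accuracy=acc,
    )
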