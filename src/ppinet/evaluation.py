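"""Simulated-prospective evaluation of link scores.

Scores assigned to the training non-edges are compared against the newly
reported interactions of the later snapshot: ROC/AUROC, operating points at
benchmark specificities (0.99 / 0.95 / 0.90) with sensitivity, PPV and lift,
DeLong's paired test for comparing two models' ROC curves, Venn-style overlap
of prediction sets, and the high-specificity threshold-intersection heuristic
that keeps only candidates above the training-non-edge percentile of every
covariate simultaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "ROCResult",
    "OperatingPoint",
    "roc_auroc",
    "operating_point",
    "compare_auroc",
    "prediction_overlap",
    "threshold_intersection",
    "nearest_rank_percentile",
]

BENCHMARK_SPECIFICITIES = (0.99, 0.95, 0.90)


@dataclass
class ROCResult:
    thresholds: np.ndarray   # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


@dataclass
class OperatingPoint:
    """Confusion counts and derived rates at one score threshold."""

    target_specificity: float
    threshold: float
    specificity: float
    sensitivity: float
    ppv: float
    lift: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return {
            "target_specificity": self.target_specificity,
            "threshold": self.threshold,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "lift": self.lift,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        }


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present in the labels")
    return scores, labels


def roc_auroc(scores, labels) -> ROCResult:
    """ROC curve over all distinct thresholds and tie-corrected AUROC.

    The AUROC equals the Mann-Whitney statistic: the probability that a
    random positive outscores a random negative, ties counting one half.
    """
    scores, labels = _validate(scores, labels)
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auroc=float(roc_auc_score(labels, scores)),
    )


def operating_point(scores, labels, target_specificity: float) -> OperatingPoint:
    """Operating point at the smallest threshold with specificity >= target.

    A pair is predicted positive when its score is >= the threshold; the
    smallest qualifying cut maximizes sensitivity subject to the specificity
    constraint.  Lift is PPV over the prevalence of positives — the
    fold-reduction of the candidate search space.
    """
    if not 0.0 < target_specificity < 1.0:
        raise ValueError("target specificity must be in (0, 1)")
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    cuts = np.unique(scores)  # ascending
    neg_scores = np.sort(scores[labels == 0])
    # specificity at cut t: fraction of negatives with score < t — nondecreasing
    # in t, so the smallest qualifying cut is found by scanning upward.
    fp_at = n_neg - np.searchsorted(neg_scores, cuts, side="left")
    spec_at = (n_neg - fp_at) / n_neg
    ok = np.flatnonzero(spec_at >= target_specificity)
    if ok.size:
        threshold = float(cuts[ok[0]])
    else:
        threshold = float(np.nextafter(cuts[-1], np.inf))  # predict nothing
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = n_pos - tp
    tn = n_neg - fp
    prevalence = n_pos / labels.size
    ppv = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    return OperatingPoint(
        target_specificity=target_specificity,
        threshold=threshold,
        specificity=tn / n_neg,
        sensitivity=tp / n_pos,
        ppv=ppv,
        lift=ppv / prevalence,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


# ---------------------------------------------------------------------------
# DeLong's paired AUROC comparison

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j < len(x) and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1.0
        i = j
    return ranks

def _delong_components(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n          # structural components, positives
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # structural components, negatives
    return auc, v10, v01


def compare_auroc(scores_a, scores_b, labels) -> float:
    """Two-sided p-value for the paired AUROC difference (DeLong).

    Both score vectors must be over the same pairs with the same labels; the
    covariance between the two empirical AUROCs is estimated from the shared
    structural components, so correlated models are handled correctly.
    Identical score vectors give p = 1.
    """
    scores_a, labels = _validate(scores_a, labels)
    scores_b, _ = _validate(scores_b, labels)
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 1.0
    z = (auc_a - auc_b) / math.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def prediction_overlap(prediction_sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Venn-region counts for two or three named prediction sets.

    Keys of the result are tuples of the set names whose exclusive
    intersection the count describes; the regions partition the union.
    """
    names = list(prediction_sets)
    if len(names) not in (2, 3):
        raise ValueError("prediction_overlap expects 2 or 3 named sets")
    sets = {k: set(v) for k, v in prediction_sets.items()}
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            region = set.intersection(*(sets[k] for k in inside))
            for out in names:
                if out not in inside:
                    region -= sets[out]
            regions[tuple(inside)] = len(region)
    return regions


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p*n)-th smallest value."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("empty value set")
    rank = max(1, math.ceil(percentile * values.size))
    return float(values[rank - 1])


def threshold_intersection(
    covariate_scores: Mapping[str, Mapping[tuple, float]],
    training_nonedge_scores: Mapping[str, Sequence[float]],
    percentile: float,
) -> tuple[set, dict[str, float]]:
    """High-specificity heuristic: intersect per-covariate percentile filters.

    Each named covariate gets a threshold at the given percentile of its
    values over the *training* non-edges (nearest-rank); the prediction set
    is the candidate pairs strictly above every threshold simultaneously.
    A covariate constant over the training non-edges carries no
    discrimination and is excluded from the filter rather than (with the
    strict cut) vetoing every pair.  Returns ``(predicted_pairs,
    thresholds)``.
    """
    if not 0.0 <= percentile < 1.0:
        raise ValueError("percentile must be in [0, 1)")
    names = list(covariate_scores)
    if set(training_nonedge_scores) != set(names):
        raise ValueError("candidate and training covariate names must match")
    universes = [set(covariate_scores[k]) for k in names]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("all covariate vectors must cover the same pair universe")
    for k in names:
        if len(training_nonedge_scores[k]) == 0:
            raise ValueError("empty training non-edge set")
    if percentile == 0.0:
        # degenerate case: no value is excluded by rank, so the cut sits at 0
        # and the strict filter keeps exactly the pairs positive on every
        # (nonnegative) covariate
        thresholds = {k: 0.0 for k in names}
    else:
        thresholds = {
            k: nearest_rank_percentile(
                np.asarray(list(training_nonedge_scores[k]), dtype=float), percentile)
            for k in names
        }
    active = [k for k in names
              if np.ptp(np.asarray(list(training_nonedge_scores[k]), dtype=float)) > 0]
    predicted = {
        pair for pair in universes[0]
        if all(covariate_scores[k][pair] > thresholds[k] for k in active)
    }
    return predicted, thresholds
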