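"""Discrimination metrics for integer risk scores.

AUC is computed as the rank statistic — the probability that a random
outcome-positive case outscores a random negative one, ties counted a
half — which equals the trapezoidal area under the empirical ROC curve.
Confidence intervals come from a percentile case-resampling bootstrap;
the operating threshold defaults to the ROC point nearest the
upper-left corner, classifying ``score >= threshold`` as positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


class MetricError(ValueError):
    pass


def _check_classes(outcome: np.ndarray) -> np.ndarray:
    y = np.asarray(outcome)
    if not ((y == 1).any() and (y == 0).any()):
        raise MetricError("both outcome classes must be present")
    return y


def auc(scores: np.ndarray, outcome: np.ndarray) -> float:
    """Rank-statistic AUC (Mann–Whitney form), ties counted 1/2."""
    y = _check_classes(outcome)
    s = np.asarray(scores, dtype=float)
    r = stats.rankdata(s)
    n_pos = int((y == 1).sum())
    n_neg = len(y) - n_pos
    u = r[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_curve(scores: np.ndarray, outcome: np.ndarray):
    """Sensitivity/specificity at every candidate threshold.

    Thresholds are the sorted unique scores (rule: predict positive when
    ``score >= t``), plus one above the maximum so the all-negative
    operating point is included.
    """
    y = _check_classes(outcome)
    s = np.asarray(scores, dtype=float)
    uniq = np.unique(s)
    thresholds = np.concatenate([uniq, [uniq[-1] + 1]])
    pos, neg = (y == 1), (y == 0)
    sens = np.array([(s[pos] >= t).mean() for t in thresholds])
    spec = np.array([(s[neg] < t).mean() for t in thresholds])
    return thresholds, sens, spec


def bootstrap_ci(scores: np.ndarray, outcome: np.ndarray,
                 n_resamples: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Percentile 95% bootstrap CI for the AUC (cases resampled with
    replacement; a one-class resample is redrawn, at most 10 times)."""
    if n_resamples < 100:
        raise MetricError("use at least 100 bootstrap resamples")
    y = _check_classes(outcome)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    stats_ = np.empty(n_resamples)
    for b in range(n_resamples):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if (yb == 1).any() and (yb == 0).any():
                break
        else:
            raise MetricError("could not draw a two-class bootstrap resample")
        stats_[b] = auc(s[idx], yb)
    lo, hi = np.percentile(stats_, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class RocResult:
    """Full ROC analysis of a score vector: curve, AUC, CI, threshold metrics."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_lower: float
    ci_upper: float
    n_resamples: int
    seed: int
    optimal_threshold: float = np.nan
    accuracy: float = np.nan
    sens_at_threshold: float = np.nan
    spec_at_threshold: float = np.nan
    f1: float = np.nan

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "optimal_threshold": self.optimal_threshold, "accuracy": self.accuracy,
            "sensitivity": self.sens_at_threshold,
            "specificity": self.spec_at_threshold, "f1": self.f1,
        }


def optimal_threshold(roc: RocResult) -> float:
    """Threshold whose (sensitivity, specificity) point is nearest the
    ROC upper-left corner; ties resolve to the lower threshold."""
    d2 = (1 - roc.sensitivity) ** 2 + (1 - roc.specificity) ** 2
    best = np.flatnonzero(d2 == d2.min())
    return float(roc.thresholds[best[0]])


def threshold_metrics(scores: np.ndarray, outcome: np.ndarray,
                      threshold: float) -> tuple[float, float, float, float]:
    """(accuracy, sensitivity, specificity, F1) at ``score >= threshold``."""
    y = _check_classes(outcome)
    s = np.asarray(scores, dtype=float)
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    accuracy = (tp + tn) / len(y)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    if tp + fp == 0:
        warnings.warn("no predicted positives at this threshold; F1 reported as 0",
                      stacklevel=2)
        f1 = 0.0
    else:
        precision = tp / (tp + fp)
        f1 = 2 * precision * sens / (precision + sens) if precision + sens else 0.0
    return accuracy, sens, spec, f1


def evaluate_scores(scores: np.ndarray, outcome: np.ndarray,
                    n_resamples: int = 1000, seed: int = 0) -> RocResult:
    """One-call ROC analysis: curve, AUC with bootstrap CI, and metrics at
    the nearest-to-corner optimal threshold."""
    thresholds, sens, spec = roc_curve(scores, outcome)
    a = auc(scores, outcome)
    lo, hi = bootstrap_ci(scores, outcome, n_resamples=n_resamples, seed=seed)
    roc = RocResult(thresholds=thresholds, sensitivity=sens, specificity=spec,
                    auc=a, ci_lower=lo, ci_upper=hi,
                    n_resamples=n_resamples, seed=seed)
    t = optimal_threshold(roc)
    acc, se, sp, f1 = threshold_metrics(scores, outcome, t)
    roc.optimal_threshold = t
    roc.accuracy, roc.sens_at_threshold, roc.spec_at_threshold, roc.f1 = acc, se, sp, f1
    return roc
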