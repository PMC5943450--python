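"""Diagnostic-performance statistics for segment-level validation.

Implements the validation battery used to compare a continuous
diagnostic score (segment mean native T1) and a dichotomous one (LGE
segment positivity) against a reference standard: the empirical ROC
curve with trapezoidal AUC, operating-point sensitivity/specificity and
the Youden index, the Youden-optimal cutoff, the DeLong covariance
z-test for paired AUCs, Bland-Altman limits of agreement and ordinary
least-squares regression.

Positivity at a cutoff is strict (``score > cutoff``) throughout,
matching the ``> mean + k*SD`` segmentation convention. For a
dichotomous test the empirical "curve" is the single-operating-point
polygon (0,0) -> (fpr, tpr) -> (1,1), whose trapezoidal AUC equals
(sensitivity + specificity) / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "DiagnosticPerformance",
    "AgreementResult",
    "RegressionResult",
    "DelongResult",
    "roc_curve",
    "performance_at_cutoff",
    "youden_optimal_cutoff",
    "delong_compare",
    "bland_altman",
    "linear_regression",
]


@dataclass(frozen=True)
class DiagnosticPerformance:
    """ROC summary and/or a single operating point.

    ``sensitivity``/``specificity`` are percentages; ``youden_j`` is the
    fraction sens/100 + spec/100 - 1. ``roc_points`` is a list of
    (fpr, tpr, cutoff) with fpr ascending; operating-point fields are
    NaN for a curve-only result and ``auc`` NaN for a point-only one.
    """

    auc: float = float("nan")
    auc_se: float = float("nan")
    roc_points: Optional[list[tuple[float, float, float]]] = None
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    youden_j: float = float("nan")
    cutoff: float = float("nan")
    counts: Optional[tuple[int, int, int, int]] = None  # (tp, fp, tn, fn)


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman agreement of paired measurements (differences y - x)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class RegressionResult:
    """Simple (ordinary least squares) linear regression y on x."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


class DelongResult(NamedTuple):
    auc_a: float
    auc_b: float
    z: float
    p: float


def _validate_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    return labels


def _cutoff_set(scores: np.ndarray) -> np.ndarray:
    """All midpoints between adjacent distinct scores, plus +/- infinity."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([np.inf], mids[::-1], [-np.inf]))


def _confusion(scores: np.ndarray, labels: np.ndarray, cutoff: float):
    pred = scores > cutoff
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    return tp, fp, tn, fn


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values: for each positive, the fraction of
    negatives it outranks (ties 1/2), and symmetrically for negatives."""
    pos = scores[labels]
    neg = scores[~labels]
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    v10 = cmp.mean(axis=1)  # one per positive
    v01 = cmp.mean(axis=0)  # one per negative
    return v10, v01


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> DiagnosticPerformance:
    """Empirical ROC curve with trapezoidal AUC and its DeLong SE.

    Cutoffs are the midpoints between adjacent distinct scores plus
    +/- infinity, with strict ``score > cutoff`` positivity; the
    trapezoidal AUC over these points equals the normalized
    Mann-Whitney U statistic with ties counted one half. Binary 0/1
    scores therefore yield the single-operating-point dichotomous curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _validate_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be equal-length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    points = []
    for c in _cutoff_set(scores):
        tp, fp, tn, fn = _confusion(scores, labels, c)
        points.append((fp / n_neg, tp / n_pos, float(c)))
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr, fpr))
    v10, v01 = _placements(scores, labels)
    var = (np.var(v10, ddof=1) if n_pos > 1 else 0.0) / n_pos + (
        np.var(v01, ddof=1) if n_neg > 1 else 0.0
    ) / n_neg
    return DiagnosticPerformance(auc=auc, auc_se=float(math.sqrt(max(var, 0.0))), roc_points=points)


def performance_at_cutoff(
    scores: Sequence[float], labels: Sequence[bool], cutoff: float
) -> DiagnosticPerformance:
    """Sensitivity, specificity, Youden J and counts at ``score > cutoff``.

    Binary 0/1 scores pass through unchanged with any cutoff in (0, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _validate_binary(labels)
    tp, fp, tn, fn = _confusion(scores, labels, cutoff)
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    return DiagnosticPerformance(
        sensitivity=sens,
        specificity=spec,
        youden_j=sens / 100.0 + spec / 100.0 - 1.0,
        cutoff=float(cutoff),
        counts=(tp, fp, tn, fn),
    )


def youden_optimal_cutoff(
    scores: Sequence[float], labels: Sequence[bool]
) -> tuple[float, DiagnosticPerformance]:
    """Cutoff maximizing Youden's J over the ROC cutoff set.

    Ties are broken toward the smallest cutoff. Returns the cutoff and
    the full performance (ROC AUC plus the operating point) at it.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _validate_binary(labels)
    best_c, best_perf = None, None
    for c in _cutoff_set(scores):
        if not np.isfinite(c):
            continue
        perf = performance_at_cutoff(scores, labels, c)
        if (
            best_perf is None
            or perf.youden_j > best_perf.youden_j + 1e-12
            or (abs(perf.youden_j - best_perf.youden_j) <= 1e-12 and c < best_c)
        ):
            best_c, best_perf = float(c), perf
    curve = roc_curve(scores, labels)
    merged = DiagnosticPerformance(
        auc=curve.auc,
        auc_se=curve.auc_se,
        roc_points=curve.roc_points,
        sensitivity=best_perf.sensitivity,
        specificity=best_perf.specificity,
        youden_j=best_perf.youden_j,
        cutoff=best_c,
        counts=best_perf.counts,
    )
    return best_c, merged


def delong_compare(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[bool]
) -> DelongResult:
    """DeLong z-test for the difference of two paired AUCs.

    Uses the placement-value covariance estimator on the same cases for
    both scores; ``scores_b`` may be dichotomous. Two-sided p from the
    normal approximation. Identical placement structure (zero variance
    of the difference) returns z = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = _validate_binary(labels)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must be paired and equal-length")
    m = int(labels.sum())
    n = labels.size - m
    v10_a, v01_a = _placements(a, labels)
    v10_b, v01_b = _placements(b, labels)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())

    def _cov(x, y):
        if x.size < 2:
            return 0.0
        return float(np.cov(x, y, ddof=1)[0, 1])

    s10 = _cov(v10_a, v10_a) + _cov(v10_b, v10_b) - 2 * _cov(v10_a, v10_b)
    s01 = _cov(v01_a, v01_a) + _cov(v01_b, v01_b) - 2 * _cov(v01_a, v01_b)
    var = s10 / m + s01 / n
    if var <= 0:
        z = 0.0
        p = 1.0
    else:
        z = (auc_a - auc_b) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return DelongResult(auc_a=auc_a, auc_b=auc_b, z=float(z), p=float(p))


def bland_altman(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Bland-Altman agreement: bias = mean(y - x), limits of agreement
    bias +/- 1.96 * SD of the differences (SD with n - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    if x.size < 2:
        raise ValueError("Bland-Altman requires n >= 2 pairs")
    d = y - x
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=int(x.size),
    )


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x; r^2 is the squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("regression requires n >= 3")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )
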