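"""ROC evaluation of relapse predictors with tie-aware AUC and DeLong CIs.

The AUC is computed as the tie-corrected Mann-Whitney probability
``P(score_pos > score_neg) + 0.5 P(score_pos = score_neg)``, which equals
the trapezoidal area under the empirical ROC curve (including at ties).
Confidence intervals come from DeLong's structural-component variance
estimator by default, or a seeded stratified bootstrap. The operating
cut-off is chosen by the Youden index (maximal sensitivity + specificity),
with ties broken toward higher specificity; classification at a cut-off is
strict (test-positive iff score > cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["ROCResult", "DiagnosticMetrics", "roc_auc", "youden_cutoff",
           "confusion_metrics"]


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    ci95: tuple[float, float]
    scores: np.ndarray
    labels: np.ndarray


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Confusion-matrix diagnostics at a fixed cut-off, on the percent scale."""

    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float     # NaN when no predicted positives
    npv: float     # NaN when no predicted negatives
    tp: int
    fp: int
    tn: int
    fn: int


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return scores, labels


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    # tie-corrected rank statistic: midranks of positives
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    rank_sum = ranks[labels].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _delong_ci(scores: np.ndarray, labels: np.ndarray, auc: float) -> tuple[float, float]:
    """DeLong variance of the AUC via placement values (structural components)."""
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([
        (np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos
    ])
    v01 = np.array([
        (np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg
    ])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def _bootstrap_ci(
    scores: np.ndarray, labels: np.ndarray, seed: int, n_boot: int = 2000
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels)
    neg_idx = np.flatnonzero(~labels)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([
            rng.choice(pos_idx, len(pos_idx), replace=True),
            rng.choice(neg_idx, len(neg_idx), replace=True),
        ])
        aucs[b] = _mann_whitney_auc(scores[idx], labels[idx])
    lo, hi = np.quantile(aucs, [0.025, 0.975])
    return float(lo), float(hi)


def roc_auc(
    scores,
    labels,
    ci_method: str = "delong",
    seed: int = 0,
    n_boot: int = 2000,
) -> ROCResult:
    """ROC curve and AUC of a predictor against binary labels.

    Parameters
    ----------
    ci_method : {"delong", "bootstrap"}
        DeLong's asymptotic CI (default) or a seeded stratified bootstrap
        percentile interval.
    """
    scores, labels = _validate(scores, labels)
    fpr, tpr, thresholds = _sk_roc_curve(labels.astype(int), scores)
    auc = _mann_whitney_auc(scores, labels)
    if ci_method == "delong":
        ci = _delong_ci(scores, labels, auc)
    elif ci_method == "bootstrap":
        ci = _bootstrap_ci(scores, labels, seed, n_boot)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ROCResult(thresholds, tpr, fpr, auc, ci, scores, labels)


def youden_cutoff(roc: ROCResult) -> float:
    """Cut-off maximizing the Youden index ``sensitivity + specificity - 1``.

    Candidate cut-offs are the midpoints between consecutive distinct score
    values plus the extremes; a sample is test-positive when its score
    strictly exceeds the cut-off. Ties in the Youden index are broken
    toward higher specificity (then toward the higher cut-off).
    """
    scores, labels = roc.scores, roc.labels
    uniq = np.unique(scores)
    candidates = [uniq[0] - 1.0]
    candidates.extend((uniq[:-1] + uniq[1:]) / 2.0)
    candidates.append(uniq[-1])
    best = None
    for c in candidates:
        pred = scores > c
        tpr = float(pred[labels].mean())
        fpr = float(pred[~labels].mean())
        key = (tpr - fpr, -fpr, c)
        if best is None or key > best[0]:
            best = (key, c)
    return float(best[1])


def confusion_metrics(
    scores, labels, cutoff: float, strict_greater: bool = True
) -> DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV at a cut-off, as percentages.

    ``strict_greater=True`` (default) calls a sample test-positive when its
    score strictly exceeds the cut-off. PPV/NPV are NaN when there are no
    predicted positives/negatives.
    """
    scores, labels = _validate(scores, labels)
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    pred = scores > cutoff if strict_greater else scores >= cutoff
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) else float("nan")
    npv = 100.0 * tn / (tn + fn) if (tn + fn) else float("nan")
    return DiagnosticMetrics(float(cutoff), sens, spec, ppv, npv, tp, fp, tn, fn)
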