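"""Discrimination, calibration, interval estimation and paired comparisons.

AUC with DeLong placement-value variance and the paired DeLong test, the
Brier score with a Wald interval on the mean squared error, Wilson score
intervals for sensitivity and specificity, a paired difference in correct
classification proportions with a discordant-pair (McNemar-style) variance,
and the odds-ratio / sensitivity / specificity identity
OR = sens/(1-sens) * spec/(1-spec).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint

Z95 = norm.ppf(0.975)


@dataclass
class EvalReport:
    """Discrimination/calibration summary of one rule on one dataset."""

    n_cases: int
    n_controls: int
    auc: Optional[float] = None
    auc_ci: Optional[tuple[float, float]] = None
    brier: Optional[float] = None
    brier_ci: Optional[tuple[float, float]] = None
    sensitivity: Optional[float] = None
    sensitivity_ci: Optional[tuple[float, float]] = None
    specificity: Optional[float] = None
    specificity_ci: Optional[tuple[float, float]] = None
    youden_j: Optional[float] = None
    threshold: Optional[float] = None


@dataclass
class ComparisonResult:
    """Paired comparison of two rules on the same subjects."""

    delta_auc: Optional[float] = None
    delta_auc_p: Optional[float] = None
    delta_correct: Optional[float] = None
    delta_correct_ci: Optional[tuple[float, float]] = None


# ----------------------------------------------------------------------
# DeLong machinery
# ----------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray):
    """Midrank placement values V10 (per case) and V01 (per control).

    auc = mean(V10) = mean(V01); their empirical variances feed the DeLong
    variance/covariance estimates.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    r_all = rankdata(np.concatenate([x, y]), method="average")
    r_x = rankdata(x, method="average")
    r_y = rankdata(y, method="average")
    v10 = (r_all[:m] - r_x) / n
    v01 = 1.0 - (r_all[m:] - r_y) / m
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """ROC points, AUC (Mann-Whitney with midrank ties) and a 95% CI.

    The ROC polygon is returned as an array of (1 - specificity,
    sensitivity) rows over all distinct cut-offs.  The default CI is the
    Wald interval from the DeLong variance, truncated to [0, 1];
    ``ci_method="bootstrap"`` gives a stratified percentile bootstrap
    interval instead.
    """
    auc, v10, v01 = _placements(scores, labels)
    m, n = v10.size, v01.size
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        scores_arr = np.asarray(scores, dtype=float)
        labels_arr = np.asarray(labels)
        x = scores_arr[labels_arr == 1]
        y = scores_arr[labels_arr == 0]
        lb = np.repeat([1, 0], [m, n])
        reps = np.empty(n_boot)
        for b in range(n_boot):
            sb = np.concatenate(
                [x[rng.integers(0, m, m)], y[rng.integers(0, n, n)]]
            )
            reps[b] = _placements(sb, lb)[0]
        ci = (float(np.quantile(reps, 0.025)), float(np.quantile(reps, 0.975)))
    elif ci_method == "delong":
        var = (v10.var(ddof=1) / m if m > 1 else 0.0) + (
            v01.var(ddof=1) / n if n > 1 else 0.0
        )
        half = Z95 * np.sqrt(var)
        ci = (max(0.0, auc - half), min(1.0, auc + half))
    else:
        raise ValueError(f"unknown ci_method: {ci_method}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cuts = np.unique(scores)[::-1]
    sens = [( (scores >= c) & (labels == 1)).sum() / m for c in cuts]
    fpr = [((scores >= c) & (labels == 0)).sum() / n for c in cuts]
    points = np.column_stack([[0.0] + fpr + [1.0], [0.0] + sens + [1.0]])
    return points, auc, ci


def delong_compare(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> ComparisonResult:
    """Paired DeLong z-test of the AUC difference of two scores on the same
    subjects; two-sided p-value."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must have matching lengths")
    auc_a, v10_a, v01_a = _placements(scores_a, labels)
    auc_b, v10_b, v01_b = _placements(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    diff = auc_a - auc_b
    s10 = np.cov(np.stack([v10_a, v10_b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b])) if n > 1 else np.zeros((2, 2))
    var = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
    return ComparisonResult(delta_auc=float(diff), delta_auc_p=p)


# ----------------------------------------------------------------------
# Brier score
# ----------------------------------------------------------------------

def brier_score(
    probs: np.ndarray, labels: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Mean squared difference between outcome and predicted probability.

    95% Wald CI from the sample variance of the squared errors, truncated
    to [0, 1].
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    sq = (labels - probs) ** 2
    bs = float(sq.mean())
    n = sq.size
    var = sq.var(ddof=1) / n if n > 1 else 0.0
    half = Z95 * np.sqrt(var)
    return bs, (max(0.0, bs - half), min(1.0, bs + half))


# ----------------------------------------------------------------------
# Sensitivity / specificity with Wilson intervals
# ----------------------------------------------------------------------

def wilson_interval(x: int, n: int) -> tuple[float, float]:
    """Wilson score 95% interval for x successes out of n."""
    lo, hi = proportion_confint(x, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def sens_spec_wilson(
    pred_labels: np.ndarray, labels: np.ndarray
) -> tuple[tuple[float, tuple[float, float]], tuple[float, tuple[float, float]]]:
    """Sensitivity and specificity of a binary rule, each with a Wilson
    score 95% CI.  Returns ((sens, ci), (spec, ci))."""
    pred = np.asarray(pred_labels).astype(int)
    y = np.asarray(labels).astype(int)
    n_cases = int((y == 1).sum())
    n_controls = int((y == 0).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("both classes must be present")
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    sens = tp / n_cases
    spec = tn / n_controls
    return (sens, wilson_interval(tp, n_cases)), (spec, wilson_interval(tn, n_controls))


# ----------------------------------------------------------------------
# Paired difference in correct classification
# ----------------------------------------------------------------------

def compare_correct(
    pred_a: np.ndarray, pred_b: np.ndarray, labels: np.ndarray
) -> ComparisonResult:
    """Difference in proportions correctly classified by two rules on the
    same subjects, with a 95% CI from the discordant-pair decomposition.

    With n10 subjects correct under A only and n01 correct under B only,
    d = (n10 - n01)/n and var(d) = (n10 + n01 - (n10 - n01)^2/n) / n^2
    (the McNemar-style paired variance).
    """
    pred_a = np.asarray(pred_a).astype(int)
    pred_b = np.asarray(pred_b).astype(int)
    y = np.asarray(labels).astype(int)
    if not (pred_a.shape == pred_b.shape == y.shape):
        raise ValueError("predictions and labels must have matching lengths")
    ok_a = pred_a == y
    ok_b = pred_b == y
    n = y.size
    n10 = int((ok_a & ~ok_b).sum())
    n01 = int((~ok_a & ok_b).sum())
    d = (n10 - n01) / n
    var = (n10 + n01 - (n10 - n01) ** 2 / n) / n**2
    half = Z95 * np.sqrt(max(var, 0.0))
    return ComparisonResult(
        delta_correct=float(d),
        delta_correct_ci=(max(-1.0, d - half), min(1.0, d + half)),
    )


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: Optional[float] = None,
    is_probability: bool = False,
) -> EvalReport:
    """One-stop evaluation of a continuous rule on one dataset.

    AUC with DeLong CI always; Brier score when the scores are
    probabilities; sensitivity/specificity with Wilson CIs when a
    classification threshold (score >= threshold => case) is given.
    """
    labels = np.asarray(labels).astype(int)
    rep = EvalReport(
        n_cases=int((labels == 1).sum()), n_controls=int((labels == 0).sum())
    )
    _, rep.auc, rep.auc_ci = roc_auc(scores, labels)
    if is_probability:
        rep.brier, rep.brier_ci = brier_score(scores, labels)
    if threshold is not None:
        pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
        (rep.sensitivity, rep.sensitivity_ci), (rep.specificity, rep.specificity_ci) = (
            sens_spec_wilson(pred, labels)
        )
        rep.youden_j = rep.sensitivity + rep.specificity - 1.0
        rep.threshold = float(threshold)
    return rep


# ----------------------------------------------------------------------
# OR / sensitivity / specificity identity
# ----------------------------------------------------------------------

def or_sens_spec(sens: float, spec: float) -> float:
    """OR = sens/(1-sens) * spec/(1-spec); undefined at the boundaries."""
    if not (0.0 < sens < 1.0 and 0.0 < spec < 1.0):
        raise ValueError("sens and spec must lie strictly inside (0, 1)")
    return (sens / (1.0 - sens)) * (spec / (1.0 - spec))


def solve_spec(sens: float, odds_ratio: float) -> float:
    """Specificity implied by a sensitivity and an odds ratio.

    Inverting the identity gives spec = k/(1+k) with
    k = OR * (1 - sens)/sens.
    """
    if not (0.0 < sens < 1.0):
        raise ValueError("sens must lie strictly inside (0, 1)")
    if odds_ratio <= 0.0:
        raise ValueError("odds ratio must be positive")
    k = odds_ratio * (1.0 - sens) / sens
    return k / (1.0 + k)
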