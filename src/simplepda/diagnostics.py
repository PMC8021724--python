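"""Diagnostic evaluation of the score against the hsPDA label.

Empirical ROC with midpoint thresholds, trapezoidal AUC (equal to the
normalised Mann–Whitney pair statistic, ties counted 1/2), Youden-optimal
cut-off, exact Clopper–Pearson intervals for sensitivity/specificity, and
DeLong inference for single and paired AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RocEvaluation",
    "empirical_roc",
    "youden_optimal",
    "clopper_pearson",
    "sens_spec_at",
    "auc_significance",
    "delong_paired_compare",
]


class DegenerateInputError(ValueError):
    """Raised when an evaluation needs both classes and gets one."""


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError(f"scores and labels must be equal-length 1-d, got {s.shape} vs {y.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise DegenerateInputError("need at least one case and one control")
    return s, y


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval (beta quantiles).

    Returns ``(lower, upper)`` on the proportion scale; the lower bound is
    exactly 0 when ``successes == 0`` and the upper exactly 1 when
    ``successes == trials``.
    """
    if not (0 < level < 1):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    k, n = int(successes), int(trials)
    if not (0 <= k <= n) or n == 0 or successes != k or trials != n:
        raise ValueError(f"invalid counts: successes={successes}, trials={trials}")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


@dataclass
class RocEvaluation:
    """Empirical ROC for one assessment hour.

    ``thresholds`` are midpoints between consecutive distinct observed scores
    plus -inf/+inf sentinels; the decision rule is "score > threshold ⇒
    case". ``sensitivity[i]``/``specificity[i]`` correspond to
    ``thresholds[i]``, with exact 95% confidence intervals alongside.
    """

    hour: Optional[int]
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    sens_ci: np.ndarray  # (k, 2)
    spec_ci: np.ndarray  # (k, 2)
    auc: float
    optimal_cutoff: float
    n_cases: int
    n_controls: int
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    @property
    def youden(self) -> np.ndarray:
        """Youden's J (sensitivity + specificity − 1) per threshold."""
        return self.sensitivity + self.specificity - 1.0

    def summary(self) -> str:
        i = int(np.argmax(self.youden + 1e-12 * np.arange(len(self.thresholds))))
        slo, shi = self.sens_ci[i]
        plo, phi = self.spec_ci[i]
        hour = f"{self.hour} h" if self.hour is not None else "pooled"
        return (
            f"ROC at {hour}: n={self.n_cases} cases / {self.n_controls} controls\n"
            f"  AUC                {self.auc:.3f}\n"
            f"  optimal cut-off    > {self.optimal_cutoff:g} (Youden J = {self.youden[i]:.3f})\n"
            f"  sensitivity        {100 * self.sensitivity[i]:.2f}% "
            f"({100 * slo:.1f}–{100 * shi:.1f})\n"
            f"  specificity        {100 * self.specificity[i]:.2f}% "
            f"({100 * plo:.1f}–{100 * phi:.1f})"
        )


def empirical_roc(scores, labels, hour: Optional[int] = None, level: float = 0.95) -> RocEvaluation:
    """Build the empirical ROC of ``scores`` against boolean ``labels``.

    AUC is the trapezoidal area of the empirical curve, identical to the
    normalised Mann–Whitney statistic with ties counted one half.
    """
    s, y = _as_arrays(scores, labels)
    cases, controls = s[y], s[~y]
    n1, n0 = len(cases), len(controls)

    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    sens_ci = np.empty((len(thresholds), 2))
    spec_ci = np.empty((len(thresholds), 2))
    for i, t in enumerate(thresholds):
        tp = int(np.sum(cases > t))
        tn = int(np.sum(controls <= t))
        sens[i] = tp / n1
        spec[i] = tn / n0
        sens_ci[i] = clopper_pearson(tp, n1, level)
        spec_ci[i] = clopper_pearson(tn, n0, level)

    # trapezoid over the empirical curve; within tied FPR the points must be
    # ordered by TPR so vertical runs connect correctly
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))

    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    optimal = float(thresholds[best.max()])  # ties toward the higher threshold

    return RocEvaluation(
        hour=hour, thresholds=thresholds, sensitivity=sens, specificity=spec,
        sens_ci=sens_ci, spec_ci=spec_ci, auc=auc, optimal_cutoff=optimal,
        n_cases=n1, n_controls=n0, scores=s, labels=y,
    )


def youden_optimal(roc: RocEvaluation) -> float:
    """Threshold maximising J = sensitivity + specificity − 1.

    Ties are broken toward the higher threshold (higher specificity); with
    all scores equal, J is 0 everywhere and the +inf sentinel is returned.
    """
    j = roc.youden
    best = np.flatnonzero(j >= j.max() - 1e-12)
    return float(roc.thresholds[best.max()])


def sens_spec_at(scores, labels, cutoff: float, level: float = 0.95):
    """Sensitivity and specificity of the rule "score > cutoff ⇒ case".

    Returns ``((sens, (lo, hi)), (spec, (lo, hi)))`` with exact intervals.
    """
    s, y = _as_arrays(scores, labels)
    cases, controls = s[y], s[~y]
    tp = int(np.sum(cases > cutoff))
    tn = int(np.sum(controls <= cutoff))
    sens = tp / len(cases)
    spec = tn / len(controls)
    return (sens, clopper_pearson(tp, len(cases), level)), (
        spec, clopper_pearson(tn, len(controls), level))


# ---------------------------------------------------------------------------
# DeLong machinery (structural components via midranks)
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and per-subject structural components V10 (cases), V01 (controls)."""
    cases = scores[labels]
    controls = scores[~labels]
    m, n = len(cases), len(controls)
    tx = _midrank(cases)
    ty = _midrank(controls)
    tz = _midrank(np.concatenate([cases, controls]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def auc_significance(roc: RocEvaluation) -> float:
    """Two-sided p-value for H0: AUC = 0.5, using the DeLong variance."""
    auc, v10, v01 = _delong_components(roc.scores, roc.labels)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    if var <= 0:
        return 1.0 if abs(auc - 0.5) < 1e-12 else 0.0
    z = (auc - 0.5) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def delong_paired_compare(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong comparison of two AUCs measured on the same subjects.

    Returns ``(auc_a − auc_b, two-sided p)``. The statistic is symmetric in
    the two score vectors up to the sign of the difference.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise ValueError(f"score vectors differ in length: {sa.shape} vs {sb.shape}")
    _, y = _as_arrays(sa, labels)
    auc_a, v10a, v01a = _delong_components(sa, y)
    auc_b, v10b, v01b = _delong_components(sb, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = float(auc_a - auc_b)
    if var_diff <= 1e-300:
        return diff, 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var_diff)
    return diff, float(2 * stats.norm.sf(abs(z)))
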