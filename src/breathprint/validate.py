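"""External validation: diagnostic metrics, Wald CIs, 2x2 association tests.

A frozen recognition model is applied to a cohort never used in training;
truth-vs-prediction counts go into a 2x2 confusion matrix (asthma is the
positive class) from which accuracy, sensitivity, specificity, PPV and NPV
are derived.

Formatting follows the reporting conventions of small e-nose validation
studies: point estimates as percent *floored* to the integer (7/9 -> 77),
Wald intervals ``p ± 1.96 sqrt(p(1-p)/n)`` with bounds *rounded* to one
decimal and clipped to [0, 100], and a zero-width interval at the point
estimate when the proportion is degenerate (0/n or n/n).

Association between truth and prediction is tested four ways: uncorrected
Pearson chi-square, Yates continuity-corrected chi-square, single-stratum
Mantel-Haenszel chi-square ((n-1)/n times Pearson), and Fisher's exact test
(two-sided, sum of hypergeometric table probabilities not exceeding the
observed one).  A pooled/Welch two-sample t-test from summary statistics is
included for cohort-characteristics comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import BreathPrintSet
from .discriminate import DiscriminationModel, classify

__all__ = [
    "ConfusionMatrix",
    "MetricValue",
    "MetricsReport",
    "external_validate",
    "confusion_metrics",
    "wald_ci",
    "pearson_chi2",
    "yates_chi2",
    "mantel_haenszel_chi2",
    "fisher_exact",
    "t_test_from_summary",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Truth-vs-prediction counts; asthma (the positive class) first.

    Orientation: rows = truth, columns = prediction, so the 2x2 table is
    ``[[tp, fn], [fp, tn]]``.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n < 1:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)


@dataclass(frozen=True)
class MetricValue:
    numerator: int
    denominator: int
    point_percent: int  # floor(100 k / n)
    ci_low_percent: float  # 1-decimal, clipped to [0, 100]
    ci_high_percent: float


@dataclass(frozen=True)
class MetricsReport:
    confusion: ConfusionMatrix
    metrics: dict  # name -> MetricValue | None (None = undefined denominator)
    association_pvalues: dict = field(default_factory=dict)


def wald_ci(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wald binomial CI in percent, bounds rounded to one decimal.

    Degenerate proportions (k = 0 or k = n) give a zero-width interval at
    the point estimate, as the plain Wald formula implies.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    p = k / n
    se = math.sqrt(p * (1.0 - p) / n)
    low = min(max(100.0 * (p - z * se), 0.0), 100.0)
    high = min(max(100.0 * (p + z * se), 0.0), 100.0)
    return round(low, 1), round(high, 1)


def _metric(k: int, n: int, z: float) -> MetricValue | None:
    if n == 0:
        return None
    low, high = wald_ci(k, n, z)
    return MetricValue(
        numerator=k,
        denominator=n,
        point_percent=100 * k // n,
        ci_low_percent=low,
        ci_high_percent=high,
    )


def confusion_metrics(cm: ConfusionMatrix, z: float = 1.96) -> MetricsReport:
    """Accuracy, sensitivity, specificity, PPV, NPV with Wald CIs.

    A metric whose denominator is empty is reported as undefined (None),
    never as zero.
    """
    metrics = {
        "accuracy": _metric(cm.tp + cm.tn, cm.n, z),
        "sensitivity": _metric(cm.tp, cm.tp + cm.fn, z),
        "specificity": _metric(cm.tn, cm.tn + cm.fp, z),
        "ppv": _metric(cm.tp, cm.tp + cm.fp, z),
        "npv": _metric(cm.tn, cm.tn + cm.fn, z),
    }
    return MetricsReport(confusion=cm, metrics=metrics)


# -- 2x2 association tests -------------------------------------------------


def _expected(table: np.ndarray) -> np.ndarray | None:
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    if np.any(r == 0) or np.any(c == 0):
        return None
    return np.outer(r, c) / n


def pearson_chi2(cm: ConfusionMatrix) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on the 2x2, df = 1.

    A zero marginal yields statistic 0 and p = 1 by convention.
    """
    O = cm.table
    E = _expected(O)
    if E is None:
        return 0.0, 1.0
    stat = float(((O - E) ** 2 / E).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def yates_chi2(cm: ConfusionMatrix) -> tuple[float, float]:
    """Yates continuity-corrected chi-square; correction floored at 0."""
    O = cm.table
    E = _expected(O)
    if E is None:
        return 0.0, 1.0
    adj = np.maximum(np.abs(O - E) - 0.5, 0.0)
    stat = float((adj**2 / E).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def mantel_haenszel_chi2(cm: ConfusionMatrix) -> tuple[float, float]:
    """Single-stratum Mantel-Haenszel chi-square: (n-1)/n times Pearson."""
    if cm.n <= 1:
        raise ValueError("Mantel-Haenszel test needs n > 1")
    pearson_stat, _ = pearson_chi2(cm)
    stat = (cm.n - 1) / cm.n * pearson_stat
    return stat, float(stats.chi2.sf(stat, df=1))


def fisher_exact(cm: ConfusionMatrix) -> float:
    """Two-sided Fisher exact p: total probability of tables (fixed margins)
    no more likely than the observed one."""
    _, p = stats.fisher_exact(cm.table, alternative="two-sided")
    return float(min(p, 1.0))


def t_test_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics: (t, df, two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if sd1 == 0 and sd2 == 0:
        df = n1 + n2 - 2 if variant == "pooled" else float("nan")
        if mean1 == mean2:
            return 0.0, float(df), 1.0
        return math.copysign(math.inf, mean1 - mean2), float(df), 0.0
    equal_var = variant == "pooled"
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), df, float(res.pvalue)


# -- external validation ---------------------------------------------------


def external_validate(
    model: DiscriminationModel,
    prints: BreathPrintSet,
    z: float = 1.96,
    positive_class: str = "asthma",
) -> MetricsReport:
    """Classify a labelled validation cohort with a frozen model and score it."""
    if len(prints) < 1:
        raise ValueError("validation set is empty")
    counts = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    for bp in prints:
        if bp.group == "unknown":
            raise ValueError(f"print {bp.sample_id!r} is unlabelled")
        pred, _ = classify(model, bp)
        truth_pos = bp.group == positive_class
        pred_pos = pred == positive_class
        if truth_pos and pred_pos:
            counts["tp"] += 1
        elif truth_pos:
            counts["fn"] += 1
        elif pred_pos:
            counts["fp"] += 1
        else:
            counts["tn"] += 1
    cm = ConfusionMatrix(**counts)
    report = confusion_metrics(cm, z=z)
    pvalues = {
        "pearson_chi2": pearson_chi2(cm)[1],
        "yates": yates_chi2(cm)[1],
        "mantel_haenszel": mantel_haenszel_chi2(cm)[1] if cm.n > 1 else float("nan"),
        "fisher_exact": fisher_exact(cm),
    }
    return MetricsReport(confusion=cm, metrics=report.metrics, association_pvalues=pvalues)
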