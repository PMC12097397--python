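"""Diagnostic-accuracy statistics for 2x2 screening tables.

For each stay-level test definition against the severe-maternal-morbidity
label, a confusion matrix (TP, FP, FN, TN) yields:

* sensitivity ``TP/(TP+FN)`` and specificity ``TN/(FP+TN)`` with exact
  Clopper-Pearson (beta-quantile) 95% intervals;
* predictive values ``PPV = TP/(TP+FP)``, ``NPV = TN/(TN+FN)`` at the
  sample prevalence, with standard-logit intervals whose variance
  combines sensitivity, specificity and the diseased/non-diseased group
  sizes (Mercaldo's prevalence-form variance):
  ``var(logit PPV) = (1-se)/(se*n1) + sp/((1-sp)*n0)`` and
  ``var(logit NPV) = se/((1-se)*n1) + (1-sp)/(sp*n0)``;
* likelihood ratios ``PLR = se/(1-sp)``, ``NLR = (1-se)/sp`` with
  log-method intervals,
  ``SE(ln PLR) = sqrt(1/TP - 1/n1 + 1/FP - 1/n0)`` and
  ``SE(ln NLR) = sqrt(1/FN - 1/n1 + 1/TN - 1/n0)``.

This triplet of interval methods reproduces, within presentation
rounding, every interval of the published validation table whose counts
are uniquely recoverable (see :data:`CANONICAL_MATRICES`).

Formatting follows the published convention: proportions as integer
percent (one decimal below 1%), ratios to one decimal (two decimals
below 0.05), half-up rounding.  Rounding is presentation-only; all
arithmetic and all test comparisons run on unrounded values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .triage import StayAssessment, TestDefinition, test_positive

__all__ = [
    "ConfusionMatrix",
    "EstimateWithCI",
    "DiagnosticReport",
    "DegenerateEstimateError",
    "ALL_DEFINITIONS",
    "CANONICAL_MATRICES",
    "PUBLISHED_ESTIMATES",
    "confusion_matrix",
    "clopper_pearson",
    "sens_spec",
    "predictive_values",
    "likelihood_ratios",
    "evaluate_matrix",
    "evaluate_cohort",
    "canonical_reports",
    "compare_to_published",
    "format_proportion",
    "format_ratio",
    "format_estimate",
    "format_report",
    "reports_to_frame",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class DegenerateEstimateError(ValueError):
    """An estimate is undefined for the given counts (e.g. no diseased)."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts of one test definition against morbidity."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class EstimateWithCI:
    """A point estimate with a two-sided confidence interval.

    ``degenerate`` marks intervals that could not be computed by the
    nominal method (a zero cell made a variance term infinite); the
    bounds then fall back to the logical limits rather than being
    silently "corrected".
    """

    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    degenerate: bool = False


@dataclass(frozen=True)
class DiagnosticReport:
    """All accuracy statistics of one test definition on one cohort."""

    label: TestDefinition
    matrix: ConfusionMatrix
    sensitivity: EstimateWithCI
    specificity: EstimateWithCI
    ppv: EstimateWithCI
    npv: EstimateWithCI
    plr: EstimateWithCI
    nlr: EstimateWithCI
    prevalence: float


#: Report order of the six test definitions.
ALL_DEFINITIONS = (
    TestDefinition.MEOWS_RED_OR_YELLOW,
    TestDefinition.MEOWS_RED,
    TestDefinition.MEOWS_YELLOW,
    TestDefinition.MEOWS_GREEN,
    TestDefinition.EWS_GE_2,
    TestDefinition.EWS_GE_4,
)


def confusion_matrix(
    assessments: Sequence[StayAssessment], definition: TestDefinition
) -> ConfusionMatrix:
    """Cross-tabulate stay-level test results against morbidity."""
    if not assessments:
        raise ValueError("no assessments")
    tp = fp = fn = tn = 0
    for a in assessments:
        positive = test_positive(a, definition)
        if positive and a.morbidity:
            tp += 1
        elif positive:
            fp += 1
        elif a.morbidity:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


def clopper_pearson(x: int, n: int, level: float = 0.95) -> EstimateWithCI:
    """Exact binomial (Clopper-Pearson) interval via beta quantiles."""
    if n < 1:
        raise DegenerateEstimateError("binomial interval undefined for n = 0")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return EstimateWithCI(x / n, lo, hi, level)


def sens_spec(m: ConfusionMatrix) -> tuple[EstimateWithCI, EstimateWithCI]:
    """Sensitivity and specificity with Clopper-Pearson intervals."""
    if m.n_diseased < 1 or m.n_healthy < 1:
        raise DegenerateEstimateError(
            "sensitivity/specificity need at least one diseased and one "
            f"non-diseased subject (got {m.n_diseased} and {m.n_healthy})"
        )
    return clopper_pearson(m.tp, m.n_diseased), clopper_pearson(m.tn, m.n_healthy)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _inv_logit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def predictive_values(m: ConfusionMatrix) -> tuple[EstimateWithCI, EstimateWithCI]:
    """PPV and NPV at the sample prevalence, with standard-logit intervals.

    When sensitivity or specificity sits at 0 or 1 a variance term blows
    up; the affected interval is returned with the logical [0, 1] bounds
    and flagged degenerate instead.
    """
    if m.tp + m.fp < 1:
        raise DegenerateEstimateError("PPV undefined: no test positives")
    if m.fn + m.tn < 1:
        raise DegenerateEstimateError("NPV undefined: no test negatives")
    n1, n0 = m.n_diseased, m.n_healthy
    if n1 < 1 or n0 < 1:
        raise DegenerateEstimateError("predictive-value CIs need both groups")
    se = m.tp / n1
    sp = m.tn / n0
    ppv_point = m.tp / (m.tp + m.fp)
    npv_point = m.tn / (m.tn + m.fn)

    def interval(point: float, var: float) -> EstimateWithCI:
        if not (0.0 < point < 1.0) or not math.isfinite(var):
            return EstimateWithCI(point, 0.0, 1.0, degenerate=True)
        half = Z95 * math.sqrt(var)
        return EstimateWithCI(
            point, _inv_logit(_logit(point) - half), _inv_logit(_logit(point) + half)
        )

    var_ppv = (
        (1 - se) / (se * n1) + sp / ((1 - sp) * n0)
        if 0.0 < se and sp < 1.0
        else math.inf
    )
    var_npv = (
        se / ((1 - se) * n1) + (1 - sp) / (sp * n0)
        if se < 1.0 and sp > 0.0
        else math.inf
    )
    return interval(ppv_point, var_ppv), interval(npv_point, var_npv)


def likelihood_ratios(m: ConfusionMatrix) -> tuple[EstimateWithCI, EstimateWithCI]:
    """Positive and negative likelihood ratios with log-method intervals.

    ``FP = 0`` makes the PLR infinite (flagged); ``FN = 0`` puts the NLR
    point at 0 with a 0 lower bound by convention (flagged).
    """
    if m.n_diseased < 1 or m.n_healthy < 1:
        raise DegenerateEstimateError("likelihood ratios need both groups")
    n1, n0 = m.n_diseased, m.n_healthy
    se = m.tp / n1
    sp = m.tn / n0

    if sp >= 1.0:  # fp == 0
        plr = EstimateWithCI(math.inf, math.inf, math.inf, degenerate=True)
    else:
        point = se / (1 - sp)
        if m.tp == 0:
            plr = EstimateWithCI(0.0, 0.0, math.inf, degenerate=True)
        else:
            se_ln = math.sqrt(1 / m.tp - 1 / n1 + 1 / m.fp - 1 / n0)
            plr = EstimateWithCI(
                point,
                point * math.exp(-Z95 * se_ln),
                point * math.exp(Z95 * se_ln),
            )

    if sp <= 0.0:  # tn == 0
        nlr = EstimateWithCI(math.inf, math.inf, math.inf, degenerate=True)
    else:
        point = (1 - se) / sp
        if m.fn == 0:
            nlr = EstimateWithCI(0.0, 0.0, math.inf, degenerate=True)
        else:
            se_ln = math.sqrt(1 / m.fn - 1 / n1 + 1 / m.tn - 1 / n0)
            nlr = EstimateWithCI(
                point,
                point * math.exp(-Z95 * se_ln),
                point * math.exp(Z95 * se_ln),
            )
    return plr, nlr


def evaluate_matrix(m: ConfusionMatrix, label: TestDefinition) -> DiagnosticReport:
    """Full report (all six statistics with CIs) for one confusion matrix."""
    sens, spec = sens_spec(m)
    ppv, npv = predictive_values(m)
    plr, nlr = likelihood_ratios(m)
    return DiagnosticReport(
        label=TestDefinition(label),
        matrix=m,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        plr=plr,
        nlr=nlr,
        prevalence=m.n_diseased / m.n,
    )


def evaluate_cohort(assessments: Sequence[StayAssessment]) -> list[DiagnosticReport]:
    """Evaluate all six test definitions over a cohort of stay assessments."""
    if not assessments:
        raise ValueError("no assessments")
    n_morbid = sum(a.morbidity for a in assessments)
    n_healthy = len(assessments) - n_morbid
    if n_morbid == 0 or n_healthy == 0:
        undefined = (
            "sensitivity, PLR, NLR (no morbid women)"
            if n_morbid == 0
            else "specificity, PLR, NLR (no non-morbid women)"
        )
        raise DegenerateEstimateError(
            f"degenerate cohort: {undefined}; predictive values unreliable"
        )
    return [
        evaluate_matrix(confusion_matrix(assessments, d), d) for d in ALL_DEFINITIONS
    ]


# ---------------------------------------------------------------------------
# Presentation formatting (published-table convention)
# ---------------------------------------------------------------------------


def _half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_proportion(p: float, decimals: int | None = None) -> str:
    """Percent string; integer percent, one decimal below 1%."""
    if decimals is None:
        decimals = 1 if p < 0.01 else 0
    return f"{_half_up(p * 100.0, decimals):.{decimals}f}%"


def format_ratio(r: float) -> str:
    """Ratio to one decimal; two decimals below 0.05; 'inf' if unbounded."""
    if math.isinf(r):
        return "inf"
    decimals = 2 if r < 0.05 else 1
    return f"{_half_up(r, decimals):.{decimals}f}"


def format_estimate(est: EstimateWithCI, kind: str) -> str:
    """Render ``point (low-high)`` in the published style.

    ``kind`` is ``"proportion"`` or ``"ratio"``.  For proportions the
    number of decimals is driven by the point estimate (a sub-1% PPV is
    shown with one decimal throughout its interval); ratios pick decimals
    value by value.
    """
    if kind == "proportion":
        decimals = 1 if est.point < 0.01 else 0
        return (
            f"{format_proportion(est.point, decimals)} "
            f"({format_proportion(est.ci_low, decimals)}-"
            f"{format_proportion(est.ci_high, decimals)})"
        )
    if kind == "ratio":
        return (
            f"{format_ratio(est.point)} "
            f"({format_ratio(est.ci_low)}-{format_ratio(est.ci_high)})"
        )
    raise ValueError(f"unknown estimate kind {kind!r}")


_STAT_KINDS = (
    ("sensitivity", "proportion"),
    ("specificity", "proportion"),
    ("ppv", "proportion"),
    ("npv", "proportion"),
    ("plr", "ratio"),
    ("nlr", "ratio"),
)


def format_report(report: DiagnosticReport) -> dict[str, str]:
    """Formatted strings for every statistic of one report."""
    out = {"test": report.label.value}
    for stat, kind in _STAT_KINDS:
        out[stat] = format_estimate(getattr(report, stat), kind)
    out["prevalence"] = format_proportion(report.prevalence, decimals=1)
    return out


def reports_to_frame(reports: Iterable[DiagnosticReport]) -> pd.DataFrame:
    """Raw and formatted values of several reports as a tidy DataFrame."""
    rows = []
    for r in reports:
        row: dict = {
            "test": r.label.value,
            "tp": r.matrix.tp,
            "fp": r.matrix.fp,
            "fn": r.matrix.fn,
            "tn": r.matrix.tn,
            "prevalence": r.prevalence,
        }
        for stat, kind in _STAT_KINDS:
            est: EstimateWithCI = getattr(r, stat)
            row[stat] = est.point
            row[f"{stat}_ci_low"] = est.ci_low
            row[f"{stat}_ci_high"] = est.ci_high
            row[f"{stat}_formatted"] = format_estimate(est, kind)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Published reference values of the validation study
# ---------------------------------------------------------------------------

#: Canonical 2x2 counts recovered by integer enumeration from the published
#: accuracy table of the validation study (723 postpartum women, 24 with
#: severe maternal morbidity).  The red and EWS>=4 rows are uniquely
#: determined by the printed values; the remaining rows are the consistent
#: solution in which the four MEOWS strata partition the 699 non-morbid
#: women as 6 + 259 + 294 + 140.  The enumeration is re-run in the test
#: suite.
CANONICAL_MATRICES: Mapping[TestDefinition, ConfusionMatrix] = {
    TestDefinition.MEOWS_RED_OR_YELLOW: ConfusionMatrix(22, 265, 2, 434),
    TestDefinition.MEOWS_RED: ConfusionMatrix(14, 6, 10, 693),
    TestDefinition.MEOWS_YELLOW: ConfusionMatrix(8, 259, 16, 440),
    TestDefinition.MEOWS_GREEN: ConfusionMatrix(2, 294, 22, 405),
    TestDefinition.EWS_GE_2: ConfusionMatrix(15, 238, 9, 461),
    TestDefinition.EWS_GE_4: ConfusionMatrix(2, 6, 22, 693),
}

#: Number of non-morbid women in the NONE stratum under the canonical
#: reconstruction (no morbid woman stayed at a score of 0 all stay).
CANONICAL_NONE_STRATUM = (0, 140)

#: The published accuracy table, verbatim (ASCII dashes), used by the
#: ``reproduce`` command and the test suite as the external reference.
PUBLISHED_ESTIMATES: Mapping[TestDefinition, Mapping[str, str]] = {
    TestDefinition.MEOWS_RED_OR_YELLOW: {
        "sensitivity": "92% (73%-99%)",
        "specificity": "62% (58%-66%)",
        "ppv": "8% (7%-9%)",
        "npv": "100% (98%-100%)",
        "plr": "2.4 (2.1-2.8)",
        "nlr": "0.1 (0.04-0.5)",
    },
    TestDefinition.MEOWS_RED: {
        "sensitivity": "58% (37%-78%)",
        "specificity": "99% (98%-100%)",
        "ppv": "70% (50%-85%)",
        "npv": "99% (98%-99%)",
        "plr": "68.0 (28.6-161.5)",
        "nlr": "0.4 (0.3-0.7)",
    },
    TestDefinition.MEOWS_YELLOW: {
        "sensitivity": "33% (16%-55%)",
        "specificity": "63% (59%-67%)",
        "ppv": "3% (2%-5%)",
        "npv": "96% (95%-97%)",
        "plr": "0.9 (0.5-1.6)",
        "nlr": "1.1 (0.8-1.4)",
    },
    TestDefinition.MEOWS_GREEN: {
        "sensitivity": "8% (1%-27%)",
        "specificity": "58% (54%-62%)",
        "ppv": "0.7% (0.2%-2.5%)",
        "npv": "95% (94%-95%)",
        "plr": "0.2 (0.1-0.8)",
        "nlr": "1.6 (1.4-1.8)",
    },
    TestDefinition.EWS_GE_2: {
        "sensitivity": "63% (41%-81%)",
        "specificity": "66% (62%-69%)",
        "ppv": "6% (4%-8%)",
        "npv": "98% (97%-99%)",
        "plr": "1.8 (1.3-2.5)",
        "nlr": "0.6 (0.3-1.0)",
    },
    TestDefinition.EWS_GE_4: {
        "sensitivity": "8% (1%-27%)",
        "specificity": "99% (98%-100%)",
        "ppv": "25% (7%-61%)",
        "npv": "97% (97%-97%)",
        "plr": "9.7 (2.1-45.6)",
        "nlr": "0.9 (0.8-1.0)",
    },
}

#: Rows whose 2x2 counts are pinned down uniquely by the printed values;
#: for these the computed intervals must also match string-for-string.
UNIQUE_ROWS = (TestDefinition.MEOWS_RED, TestDefinition.EWS_GE_4)

#: Rows whose interval reproduction is additionally verified (the
#: red-or-yellow counts follow from the canonical partition).
CI_VERIFIED_ROWS = (
    TestDefinition.MEOWS_RED_OR_YELLOW,
    TestDefinition.MEOWS_RED,
    TestDefinition.EWS_GE_4,
)


def canonical_reports() -> list[DiagnosticReport]:
    """Reports computed from the canonical reconstructed matrices."""
    return [evaluate_matrix(CANONICAL_MATRICES[d], d) for d in ALL_DEFINITIONS]


def compare_to_published() -> pd.DataFrame:
    """Computed vs published strings, cell by cell.

    Returns one row per (test, statistic) with the freshly computed
    formatted value, the published value, and whether they agree.
    """
    rows = []
    for report in canonical_reports():
        formatted = format_report(report)
        for stat, _ in _STAT_KINDS:
            published = PUBLISHED_ESTIMATES[report.label][stat]
            rows.append(
                {
                    "test": report.label.value,
                    "statistic": stat,
                    "computed": formatted[stat],
                    "published": published,
                    "match": formatted[stat] == published,
                }
            )
    return pd.DataFrame(rows)
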