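"""Diagnostic-accuracy statistics: CI methods, formatting, and the
integer-enumeration reconstruction of the published table."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from meows.diagnostics import (
    ALL_DEFINITIONS,
    CANONICAL_MATRICES,
    PUBLISHED_ESTIMATES,
    CANONICAL_NONE_STRATUM,
    ConfusionMatrix,
    DegenerateEstimateError,
    clopper_pearson,
    confusion_matrix,
    evaluate_cohort,
    evaluate_matrix,
    format_estimate,
    format_proportion,
    format_ratio,
    likelihood_ratios,
    predictive_values,
    sens_spec,
)
from meows.triage import (
    EwsAlertLevel,
    StayAssessment,
    TestDefinition,
    TriageCategory,
)

from ._oracles import binom_cdf, binom_sf_inclusive


# ---------------------------------------------------------------------------
# Clopper-Pearson
# ---------------------------------------------------------------------------


def test_clopper_pearson_known_values():
    est = clopper_pearson(14, 24)
    assert est.point == pytest.approx(14 / 24)
    assert format_proportion(est.ci_low, 0) == "37%"
    assert format_proportion(est.ci_high, 0) == "78%"
    est = clopper_pearson(22, 24)
    assert format_proportion(est.ci_low, 0) == "73%"
    assert format_proportion(est.ci_high, 0) == "99%"


def test_clopper_pearson_boundary_cases():
    assert clopper_pearson(0, 10).ci_low == 0.0
    assert clopper_pearson(10, 10).ci_high == 1.0
    with pytest.raises(DegenerateEstimateError):
        clopper_pearson(0, 0)


def test_clopper_pearson_tail_equalities_exhaustive():
    """The defining property: each bound makes the opposite binomial tail
    exactly alpha/2 (checked against a math.comb tail oracle, n <= 30)."""
    for n in range(1, 31):
        for x in range(0, n + 1):
            est = clopper_pearson(x, n)
            assert est.ci_low <= est.point <= est.ci_high
            if x > 0:
                assert binom_sf_inclusive(x, n, est.ci_low) == pytest.approx(
                    0.025, abs=1e-9
                )
            if x < n:
                assert binom_cdf(x, n, est.ci_high) == pytest.approx(0.025, abs=1e-9)


def test_clopper_pearson_coverage_at_least_nominal():
    for n in (5, 12, 24, 30):
        bounds = [clopper_pearson(x, n) for x in range(n + 1)]
        for p in [i / 20 for i in range(1, 20)]:
            coverage = sum(
                math.comb(n, x) * p**x * (1 - p) ** (n - x)
                for x in range(n + 1)
                if bounds[x].ci_low <= p <= bounds[x].ci_high
            )
            assert coverage >= 0.95 - 1e-12


def test_clopper_pearson_monotone_in_successes():
    n = 24
    lows = [clopper_pearson(x, n).ci_low for x in range(n + 1)]
    highs = [clopper_pearson(x, n).ci_high for x in range(n + 1)]
    assert lows == sorted(lows)
    assert highs == sorted(highs)


@settings(max_examples=80, derandomize=True)
@given(n=st.integers(1, 200), data=st.data())
def test_clopper_pearson_agrees_with_statsmodels(n, data):
    x = data.draw(st.integers(0, n))
    est = clopper_pearson(x, n)
    lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
    assert est.ci_low == pytest.approx(float(lo), abs=1e-10)
    assert est.ci_high == pytest.approx(float(hi), abs=1e-10)


# ---------------------------------------------------------------------------
# Sens/spec, predictive values, likelihood ratios
# ---------------------------------------------------------------------------


def test_sens_spec_points():
    sens, spec = sens_spec(ConfusionMatrix(22, 265, 2, 434))
    assert format_proportion(sens.point) == "92%"
    sens, spec = sens_spec(ConfusionMatrix(14, 6, 10, 693))
    assert spec.point == pytest.approx(693 / 699)
    assert format_proportion(spec.point) == "99%"
    s, p = sens_spec(ConfusionMatrix(1, 0, 0, 1))
    assert s.point == 1.0 and p.point == 1.0


def test_sens_spec_requires_both_groups():
    with pytest.raises(DegenerateEstimateError):
        sens_spec(ConfusionMatrix(0, 5, 0, 5))


def test_predictive_values_reference_rows():
    ppv, npv = predictive_values(ConfusionMatrix(14, 6, 10, 693))
    assert ppv.point == pytest.approx(0.70)
    assert format_estimate(ppv, "proportion") == "70% (50%-85%)"
    ppv, _ = predictive_values(ConfusionMatrix(2, 6, 22, 693))
    assert format_estimate(ppv, "proportion") == "25% (7%-61%)"


def test_predictive_values_degenerate_flagged():
    ppv, npv = predictive_values(ConfusionMatrix(1, 0, 0, 1))
    assert ppv.point == 1.0 and ppv.degenerate
    assert (ppv.ci_low, ppv.ci_high) == (0.0, 1.0)


def test_likelihood_ratios_reference_rows():
    plr, nlr = likelihood_ratios(ConfusionMatrix(14, 6, 10, 693))
    assert format_estimate(plr, "ratio") == "68.0 (28.6-161.5)"
    assert format_ratio(nlr.point) == "0.4"
    plr, _ = likelihood_ratios(ConfusionMatrix(2, 6, 22, 693))
    assert format_estimate(plr, "ratio") == "9.7 (2.1-45.6)"


def test_uninformative_test_has_unit_plr():
    plr, nlr = likelihood_ratios(ConfusionMatrix(10, 10, 10, 10))
    assert plr.point == pytest.approx(1.0)
    assert nlr.point == pytest.approx(1.0)


def test_likelihood_ratio_zero_cells_flagged():
    plr, nlr = likelihood_ratios(ConfusionMatrix(5, 0, 5, 10))
    assert math.isinf(plr.point) and plr.degenerate
    plr, nlr = likelihood_ratios(ConfusionMatrix(5, 5, 0, 10))
    assert nlr.point == 0.0 and nlr.ci_low == 0.0 and nlr.degenerate


@settings(max_examples=150, derandomize=True)
@given(
    tp=st.integers(1, 400),
    fp=st.integers(1, 400),
    fn=st.integers(1, 400),
    tn=st.integers(1, 400),
)
def test_bayes_identity_and_youden(tp, fp, fn, tn):
    """PPV from counts equals PPV from (se, sp, sample prevalence); an
    informative test (positive Youden index) has PLR above and NLR below
    one, and vice versa."""
    m = ConfusionMatrix(tp, fp, fn, tn)
    se = tp / (tp + fn)
    sp = tn / (fp + tn)
    prev = (tp + fn) / m.n
    ppv, npv = predictive_values(m)
    assert ppv.point == pytest.approx(
        se * prev / (se * prev + (1 - sp) * (1 - prev)), rel=1e-12
    )
    assert npv.point == pytest.approx(
        sp * (1 - prev) / (sp * (1 - prev) + (1 - se) * prev), rel=1e-12
    )
    plr, nlr = likelihood_ratios(m)
    youden = se + sp - 1.0
    if youden > 1e-12:
        assert plr.point > 1.0 > nlr.point
    elif youden < -1e-12:
        assert plr.point < 1.0 < nlr.point


# ---------------------------------------------------------------------------
# Formatting
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "value,expected",
    [(0.9167, "92%"), (0.625, "63%"), (0.00676, "0.7%"), (0.0067568, "0.7%"), (1.0, "100%")],
)
def test_proportion_formatting(value, expected):
    assert format_proportion(value) == expected


@pytest.mark.parametrize(
    "value,expected",
    [(67.96, "68.0"), (0.0356, "0.04"), (0.13, "0.1"), (9.708, "9.7"), (0.05, "0.1")],
)
def test_ratio_formatting(value, expected):
    assert format_ratio(value) == expected


def test_half_up_rounding_not_bankers():
    assert format_proportion(0.625) == "63%"
    assert format_proportion(0.615) == "62%"


# ---------------------------------------------------------------------------
# Confusion matrices and cohort evaluation
# ---------------------------------------------------------------------------


def _assessment(wid, cat, lvl, morbid):
    return StayAssessment(wid, cat, 0, lvl, 0, morbid)


def test_confusion_matrix_basic():
    cohort = [
        _assessment("a", TriageCategory.RED, EwsAlertLevel.NONE, True),
        _assessment("b", TriageCategory.NONE, EwsAlertLevel.NONE, False),
    ]
    m = confusion_matrix(cohort, TestDefinition.MEOWS_RED)
    assert (m.tp, m.fp, m.fn, m.tn) == (1, 0, 0, 1)


def test_confusion_matrix_all_negative():
    cohort = [
        _assessment("a", TriageCategory.NONE, EwsAlertLevel.NONE, True),
        _assessment("b", TriageCategory.NONE, EwsAlertLevel.NONE, False),
    ]
    m = confusion_matrix(cohort, TestDefinition.MEOWS_RED)
    assert m.tp == 0 and m.fp == 0 and m.n == 2


def test_evaluate_cohort_degenerate():
    cohort = [_assessment("a", TriageCategory.RED, EwsAlertLevel.NONE, False)]
    with pytest.raises(DegenerateEstimateError):
        evaluate_cohort(cohort)


def test_exclusive_strata_counts_partition_cohort():
    cohort = [
        _assessment("a", TriageCategory.RED, EwsAlertLevel.EMERGENCY, True),
        _assessment("b", TriageCategory.YELLOW, EwsAlertLevel.INFORM, False),
        _assessment("c", TriageCategory.GREEN, EwsAlertLevel.NONE, False),
        _assessment("d", TriageCategory.NONE, EwsAlertLevel.NONE, True),
    ]
    tp_sum = fp_sum = 0
    for d in (
        TestDefinition.MEOWS_RED,
        TestDefinition.MEOWS_YELLOW,
        TestDefinition.MEOWS_GREEN,
    ):
        m = confusion_matrix(cohort, d)
        tp_sum += m.tp
        fp_sum += m.fp
    none_morbid = sum(
        a.morbidity and a.worst_meows is TriageCategory.NONE for a in cohort
    )
    none_healthy = sum(
        (not a.morbidity) and a.worst_meows is TriageCategory.NONE for a in cohort
    )
    assert tp_sum + none_morbid == sum(a.morbidity for a in cohort)
    assert fp_sum + none_healthy == sum(not a.morbidity for a in cohort)


# ---------------------------------------------------------------------------
# Integer-enumeration reconstruction of the published counts
# ---------------------------------------------------------------------------

N_MORBID, N_HEALTHY = 24, 699


def _formatted_row(tp, fp):
    m = ConfusionMatrix(tp, fp, N_MORBID - tp, N_HEALTHY - fp)
    try:
        r = evaluate_matrix(m, TestDefinition.MEOWS_RED)
    except DegenerateEstimateError:
        return None
    return {
        "sensitivity": format_estimate(r.sensitivity, "proportion"),
        "specificity": format_estimate(r.specificity, "proportion"),
        "ppv": format_estimate(r.ppv, "proportion"),
        "npv": format_estimate(r.npv, "proportion"),
        "plr": format_estimate(r.plr, "ratio"),
        "nlr": format_estimate(r.nlr, "ratio"),
    }


def _point_only(formatted):
    return {k: v.split(" ")[0] for k, v in formatted.items()}


def _enumerate_matches(published, require_cis):
    published_points = _point_only(published)
    matches = []
    for tp in range(N_MORBID + 1):
        # Prune on the sensitivity point before the expensive row build.
        if format_proportion(tp / N_MORBID) != published_points["sensitivity"].split(" ")[0]:
            continue
        for fp in range(N_HEALTHY + 1):
            row = _formatted_row(tp, fp)
            if row is None:
                continue
            target = published if require_cis else published_points
            candidate = row if require_cis else _point_only(row)
            if candidate == target:
                matches.append((tp, fp))
    return matches


def test_enumeration_recovers_unique_rows():
    """The printed red and EWS>=4 rows pin their 2x2 counts uniquely."""
    for d in (TestDefinition.MEOWS_RED, TestDefinition.EWS_GE_4):
        matches = _enumerate_matches(PUBLISHED_ESTIMATES[d], require_cis=True)
        canon = CANONICAL_MATRICES[d]
        assert matches == [(canon.tp, canon.fp)]


def test_enumeration_admits_canonical_counts_everywhere():
    """Every canonical matrix reproduces all published point estimates."""
    for d in ALL_DEFINITIONS:
        matches = _enumerate_matches(PUBLISHED_ESTIMATES[d], require_cis=False)
        canon = CANONICAL_MATRICES[d]
        assert (canon.tp, canon.fp) in matches


def test_canonical_partition_is_consistent():
    strata = (
        TestDefinition.MEOWS_RED,
        TestDefinition.MEOWS_YELLOW,
        TestDefinition.MEOWS_GREEN,
    )
    none_tp, none_fp = CANONICAL_NONE_STRATUM
    assert sum(CANONICAL_MATRICES[d].tp for d in strata) + none_tp == N_MORBID
    assert sum(CANONICAL_MATRICES[d].fp for d in strata) + none_fp == N_HEALTHY
    roy = CANONICAL_MATRICES[TestDefinition.MEOWS_RED_OR_YELLOW]
    assert roy.tp == sum(
        CANONICAL_MATRICES[d].tp
        for d in (TestDefinition.MEOWS_RED, TestDefinition.MEOWS_YELLOW)
    )
    assert roy.fp == sum(
        CANONICAL_MATRICES[d].fp
        for d in (TestDefinition.MEOWS_RED, TestDefinition.MEOWS_YELLOW)
    )
    for d in ALL_DEFINITIONS:
        m = CANONICAL_MATRICES[d]
        assert m.n_diseased == N_MORBID and m.n_healthy == N_HEALTHY
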