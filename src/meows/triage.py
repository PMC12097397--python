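"""Triage classification and stay-level aggregation.

A MEOWS observation score maps to one of four ordered triage strata:

* ``RED`` — total score >= 7: continuous monitoring, senior physicians
  to the bedside.
* ``YELLOW`` — total 5-6 *or* any single parameter scoring 3: intensive
  monitoring (at least every 30 min), physician notified.
* ``GREEN`` — total 1-4: lead nurse/midwife informed, monitoring may be
  intensified.
* ``NONE`` — total 0.  The charted escalation ladder starts at a score
  of 1, so score-0 observations form their own stratum below green.

The general EWS escalates on the total alone: ``INFORM`` (notify a
physician) at a total of 2 or more, ``EMERGENCY`` (call the hospital
emergency medical service) when the total exceeds 3.

A woman is evaluated over her whole high-dependency-unit stay: the
stay-level test result is her *worst* observation under each system
(the screening reading of a warning chart — one trigger anywhere in the
stay is a positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum

import numpy as np
import pandas as pd

from .scoring import (
    EWS,
    MEOWS,
    ObservationScore,
    ScoringSystem,
    VitalsObservation,
    score_table,
)

__all__ = [
    "TriageCategory",
    "EwsAlertLevel",
    "RECOMMENDED_ACTIONS",
    "DeliveryMode",
    "Covariates",
    "StayRecord",
    "StayAssessment",
    "TestDefinition",
    "meows_triage",
    "ews_alert",
    "aggregate_stay",
    "assess_frame",
    "test_positive",
]


class TriageCategory(IntEnum):
    """Ordered MEOWS triage strata (NONE < GREEN < YELLOW < RED)."""

    NONE = 0
    GREEN = 1
    YELLOW = 2
    RED = 3


class EwsAlertLevel(IntEnum):
    """Ordered general-EWS alert levels (NONE < INFORM < EMERGENCY)."""

    NONE = 0
    INFORM = 1
    EMERGENCY = 2


#: Escalation response attached to each MEOWS stratum.
RECOMMENDED_ACTIONS = {
    TriageCategory.NONE: "routine monitoring",
    TriageCategory.GREEN: "inform lead nurse/midwife; consider more intensive monitoring",
    TriageCategory.YELLOW: "measure at least every 30 min; notify physician",
    TriageCategory.RED: "continuous monitoring; senior anesthesiology and obstetric physicians to bedside",
}


def meows_triage(score: ObservationScore) -> TriageCategory:
    """MEOWS stratum for one observation score."""
    if score.total >= 7:
        return TriageCategory.RED
    if score.total in (5, 6) or score.max_single >= 3:
        return TriageCategory.YELLOW
    if score.total >= 1:
        return TriageCategory.GREEN
    return TriageCategory.NONE


def ews_alert(score: ObservationScore) -> EwsAlertLevel:
    """General-EWS alert level for one observation score."""
    if score.total >= 4:
        return EwsAlertLevel.EMERGENCY
    if score.total >= 2:
        return EwsAlertLevel.INFORM
    return EwsAlertLevel.NONE


class DeliveryMode(str, Enum):
    VAGINAL = "vaginal"
    PLANNED_CESAREAN = "planned_cesarean"
    EMERGENCY_CESAREAN = "emergency_cesarean"
    OPERATIVE_VAGINAL = "operative_vaginal"


@dataclass(frozen=True)
class Covariates:
    """Stay-level demographic and clinical covariates (all optional)."""

    age: float | None = None
    bmi_prepregnancy: float | None = None
    bmi_delivery: float | None = None
    gestational_age: float | None = None
    nulliparous: bool | None = None
    twin: bool | None = None
    delivery_mode: str | None = None
    blood_loss_ml: float | None = None
    days_in_hdu: float | None = None


@dataclass(frozen=True)
class StayRecord:
    """One woman's HDU stay: repeated observations plus her morbidity label.

    ``morbidity`` is the adjudicated severe-maternal-morbidity label and is
    consumed as-is.  ``red_override`` is the manual escalation flag for
    acute clinical deterioration that is not computable from the vitals; it
    forces the stay's worst MEOWS stratum to RED.
    """

    woman_id: str
    observations: tuple[VitalsObservation, ...]
    morbidity: bool
    covariates: Covariates | None = None
    red_override: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        if not self.observations:
            raise ValueError(f"stay {self.woman_id}: no observations")
        times = [o.timestamp for o in self.observations]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"stay {self.woman_id}: timestamps decrease")


@dataclass(frozen=True)
class StayAssessment:
    """Per-woman aggregate: worst stratum/alert and maximal totals."""

    woman_id: str
    worst_meows: TriageCategory
    max_meows_total: int
    worst_ews: EwsAlertLevel
    max_ews_total: int
    morbidity: bool


def aggregate_stay(
    stay: StayRecord,
    meows: ScoringSystem = MEOWS,
    ews: ScoringSystem = EWS,
) -> StayAssessment:
    """Score every observation under both systems and keep the worst."""
    worst_m = TriageCategory.NONE
    worst_e = EwsAlertLevel.NONE
    max_m = 0
    max_e = 0
    for obs in stay.observations:
        sm = meows.score(obs)
        se = ews.score(obs)
        worst_m = max(worst_m, meows_triage(sm))
        worst_e = max(worst_e, ews_alert(se))
        max_m = max(max_m, sm.total)
        max_e = max(max_e, se.total)
    if stay.red_override:
        worst_m = TriageCategory.RED
    return StayAssessment(
        stay.woman_id, worst_m, max_m, worst_e, max_e, stay.morbidity
    )


def _meows_categories(totals: np.ndarray, max_single: np.ndarray) -> np.ndarray:
    return np.select(
        [totals >= 7, (totals >= 5) | (max_single >= 3), totals >= 1],
        [TriageCategory.RED, TriageCategory.YELLOW, TriageCategory.GREEN],
        default=TriageCategory.NONE,
    )


def _ews_levels(totals: np.ndarray) -> np.ndarray:
    return np.select(
        [totals >= 4, totals >= 2],
        [EwsAlertLevel.EMERGENCY, EwsAlertLevel.INFORM],
        default=EwsAlertLevel.NONE,
    )


def assess_frame(
    frame: pd.DataFrame,
    meows: ScoringSystem = MEOWS,
    ews: ScoringSystem = EWS,
) -> list[StayAssessment]:
    """Vectorised equivalent of :func:`aggregate_stay` over a cohort table.

    ``frame`` is the long-format cohort table (one row per observation,
    ``woman_id`` and ``morbidity`` columns present).  Agrees exactly with
    building StayRecords and aggregating them one at a time.
    """
    sm = score_table(frame, meows)
    se = score_table(frame, ews)
    per_obs = pd.DataFrame(
        {
            "woman_id": frame["woman_id"].to_numpy(),
            "morbidity": frame["morbidity"].to_numpy(),
            "m_cat": _meows_categories(
                sm["total"].to_numpy(), sm["max_single"].to_numpy()
            ),
            "m_tot": sm["total"].to_numpy(),
            "e_lvl": _ews_levels(se["total"].to_numpy()),
            "e_tot": se["total"].to_numpy(),
        }
    )
    grouped = per_obs.groupby("woman_id", sort=False)
    if (grouped["morbidity"].nunique() > 1).any():
        raise ValueError("conflicting morbidity labels within a woman_id")
    agg = grouped.agg(
        m_cat=("m_cat", "max"),
        m_tot=("m_tot", "max"),
        e_lvl=("e_lvl", "max"),
        e_tot=("e_tot", "max"),
        morbidity=("morbidity", "first"),
    )
    return [
        StayAssessment(
            woman_id=str(wid),
            worst_meows=TriageCategory(int(row.m_cat)),
            max_meows_total=int(row.m_tot),
            worst_ews=EwsAlertLevel(int(row.e_lvl)),
            max_ews_total=int(row.e_tot),
            morbidity=bool(row.morbidity),
        )
        for wid, row in agg.iterrows()
    ]


class TestDefinition(str, Enum):
    """The six stay-level test definitions evaluated against morbidity.

    Threshold definitions compare the enum order of the worst stratum;
    the exclusive yellow/green definitions compare equality, so that the
    four MEOWS strata {NONE, GREEN, YELLOW, RED} partition any cohort.
    """

    MEOWS_RED_OR_YELLOW = "meows_red_or_yellow"
    MEOWS_RED = "meows_red"
    MEOWS_YELLOW = "meows_yellow"
    MEOWS_GREEN = "meows_green"
    EWS_GE_2 = "ews_ge2"
    EWS_GE_4 = "ews_ge4"


def test_positive(assessment: StayAssessment, definition: TestDefinition) -> bool:
    """Whether a stay is test-positive under one of the six definitions."""
    definition = TestDefinition(definition)
    if definition is TestDefinition.MEOWS_RED_OR_YELLOW:
        return assessment.worst_meows >= TriageCategory.YELLOW
    if definition is TestDefinition.MEOWS_RED:
        return assessment.worst_meows is TriageCategory.RED
    if definition is TestDefinition.MEOWS_YELLOW:
        return assessment.worst_meows is TriageCategory.YELLOW
    if definition is TestDefinition.MEOWS_GREEN:
        return assessment.worst_meows is TriageCategory.GREEN
    if definition is TestDefinition.EWS_GE_2:
        return assessment.worst_ews >= EwsAlertLevel.INFORM
    if definition is TestDefinition.EWS_GE_4:
        return assessment.worst_ews is EwsAlertLevel.EMERGENCY
    raise ValueError(f"unknown test definition {definition!r}")
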