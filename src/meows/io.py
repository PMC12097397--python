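"""Cohort table IO: the long-format CSV schema and its validation.

One row per observation.  Fixed header names; AVPU as letters A/V/P/U;
booleans as 0/1; missing values as empty cells.  Covariate columns are
optional as a group and are constant within a woman.  Rows belonging to
one woman are gathered (in file order, sorted by timestamp within the
woman) into a :class:`~meows.triage.StayRecord`.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scoring import AVPU_LEVELS, VitalsObservation, validate_observation
from .triage import Covariates, StayRecord

__all__ = [
    "VITAL_COLUMNS",
    "CORE_COLUMNS",
    "COVARIATE_COLUMNS",
    "SchemaError",
    "CohortValidationError",
    "frame_to_stays",
    "stays_to_frame",
    "read_cohort",
    "write_cohort",
]

VITAL_COLUMNS = (
    "resp_rate",
    "spo2",
    "o2_supplement",
    "temperature",
    "sbp",
    "dbp",
    "heart_rate",
    "avpu",
    "vas_pain",
)

CORE_COLUMNS = ("woman_id", "timestamp", *VITAL_COLUMNS, "morbidity")

COVARIATE_COLUMNS = (
    "age",
    "bmi_prepregnancy",
    "bmi_delivery",
    "gestational_age",
    "nulliparous",
    "twin",
    "delivery_mode",
    "blood_loss_ml",
    "days_in_hdu",
)

_BOOL_COLUMNS = ("o2_supplement", "morbidity", "nulliparous", "twin")


class SchemaError(ValueError):
    """The table does not match the documented cohort schema."""


class CohortValidationError(SchemaError):
    """Row-level value problems; ``issues`` lists them with line numbers."""

    def __init__(self, issues: Sequence[str]):
        self.issues = list(issues)
        preview = "\n".join(self.issues[:20])
        more = "" if len(self.issues) <= 20 else f"\n... and {len(self.issues) - 20} more"
        super().__init__(f"{len(self.issues)} invalid row(s):\n{preview}{more}")


def _missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def _opt_bool(value) -> bool | None:
    if _missing(value):
        return None
    return bool(int(value)) if not isinstance(value, (bool, np.bool_)) else bool(value)


def _opt_float(value) -> float | None:
    return None if _missing(value) else float(value)


def _opt_str(value) -> str | None:
    return None if _missing(value) else str(value)


def frame_to_stays(frame: pd.DataFrame) -> list[StayRecord]:
    """Build validated StayRecords from a long-format cohort table.

    Raises :class:`SchemaError` for missing columns or conflicting
    morbidity labels and :class:`CohortValidationError` (with 1-based
    data line numbers, header = line 1) for invalid vital-sign values.
    """
    missing_cols = [c for c in CORE_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {missing_cols}")
    has_covariates = all(c in frame.columns for c in COVARIATE_COLUMNS)

    issues: list[str] = []
    observations: dict[str, list[VitalsObservation]] = {}
    morbidity: dict[str, bool] = {}
    covariates: dict[str, Covariates | None] = {}
    conflicts: set[str] = set()

    for pos, row in enumerate(frame.itertuples(index=False)):
        line = pos + 2  # header is line 1
        wid = str(getattr(row, "woman_id"))
        morb = _opt_bool(getattr(row, "morbidity"))
        if morb is None:
            issues.append(f"line {line}: missing morbidity label")
            continue
        obs = VitalsObservation(
            woman_id=wid,
            timestamp=float(getattr(row, "timestamp")),
            resp_rate=_opt_float(getattr(row, "resp_rate")),
            spo2=_opt_float(getattr(row, "spo2")),
            o2_supplement=_opt_bool(getattr(row, "o2_supplement")),
            temperature=_opt_float(getattr(row, "temperature")),
            sbp=_opt_float(getattr(row, "sbp")),
            dbp=_opt_float(getattr(row, "dbp")),
            heart_rate=_opt_float(getattr(row, "heart_rate")),
            avpu=_opt_str(getattr(row, "avpu")),
            vas_pain=_opt_float(getattr(row, "vas_pain")),
        )
        row_issues = [
            i for i in validate_observation(obs) if i.kind in ("range", "non_finite", "type")
        ]
        if row_issues:
            for issue in row_issues:
                issues.append(f"line {line}: {issue.message}")
            continue
        if wid in morbidity and morbidity[wid] != morb:
            conflicts.add(wid)
        morbidity[wid] = morb
        observations.setdefault(wid, []).append(obs)
        if wid not in covariates:
            covariates[wid] = (
                Covariates(
                    age=_opt_float(getattr(row, "age")),
                    bmi_prepregnancy=_opt_float(getattr(row, "bmi_prepregnancy")),
                    bmi_delivery=_opt_float(getattr(row, "bmi_delivery")),
                    gestational_age=_opt_float(getattr(row, "gestational_age")),
                    nulliparous=_opt_bool(getattr(row, "nulliparous")),
                    twin=_opt_bool(getattr(row, "twin")),
                    delivery_mode=_opt_str(getattr(row, "delivery_mode")),
                    blood_loss_ml=_opt_float(getattr(row, "blood_loss_ml")),
                    days_in_hdu=_opt_float(getattr(row, "days_in_hdu")),
                )
                if has_covariates
                else None
            )
    if conflicts:
        raise SchemaError(
            f"conflicting morbidity labels for woman_id(s): {sorted(conflicts)}"
        )
    if issues:
        raise CohortValidationError(issues)
    return [
        StayRecord(
            woman_id=wid,
            observations=tuple(sorted(obs_list, key=lambda o: o.timestamp)),
            morbidity=morbidity[wid],
            covariates=covariates[wid],
        )
        for wid, obs_list in observations.items()
    ]


def stays_to_frame(stays: Iterable[StayRecord]) -> pd.DataFrame:
    """Long-format cohort table from StayRecords (inverse of
    :func:`frame_to_stays` up to within-woman timestamp order)."""
    rows = []
    for stay in stays:
        cov = stay.covariates or Covariates()
        for obs in stay.observations:
            rows.append(
                {
                    "woman_id": stay.woman_id,
                    "timestamp": obs.timestamp,
                    "resp_rate": obs.resp_rate,
                    "spo2": obs.spo2,
                    "o2_supplement": obs.o2_supplement,
                    "temperature": obs.temperature,
                    "sbp": obs.sbp,
                    "dbp": obs.dbp,
                    "heart_rate": obs.heart_rate,
                    "avpu": obs.avpu,
                    "vas_pain": obs.vas_pain,
                    "morbidity": stay.morbidity,
                    "age": cov.age,
                    "bmi_prepregnancy": cov.bmi_prepregnancy,
                    "bmi_delivery": cov.bmi_delivery,
                    "gestational_age": cov.gestational_age,
                    "nulliparous": cov.nulliparous,
                    "twin": cov.twin,
                    "delivery_mode": cov.delivery_mode,
                    "blood_loss_ml": cov.blood_loss_ml,
                    "days_in_hdu": cov.days_in_hdu,
                }
            )
    return pd.DataFrame(rows, columns=list(CORE_COLUMNS) + list(COVARIATE_COLUMNS))


def _encode_for_csv(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in _BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(lambda v: None if _missing(v) else int(bool(v)))
    return out


def write_cohort(stays_or_frame, path) -> None:
    """Write a cohort (StayRecords or a long-format table) as CSV.

    Booleans are written as 0/1, missing values as empty cells."""
    frame = (
        stays_or_frame
        if isinstance(stays_or_frame, pd.DataFrame)
        else stays_to_frame(stays_or_frame)
    )
    _encode_for_csv(frame).to_csv(path, index=False)


def read_cohort(path) -> list[StayRecord]:
    """Read and validate a cohort CSV into StayRecords."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # unparseable file
        raise SchemaError(f"could not parse {path}: {exc}") from exc
    return frame_to_stays(frame)
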