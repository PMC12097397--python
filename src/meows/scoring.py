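"""Declarative vital-sign scoring engines.

Two early-warning scoring systems are built in: the Modified Early
Obstetric Warning System (MEOWS), which scores nine physiological
parameters adapted to postpartum physiology, and the general adult early
warning score (EWS), which scores five.  Each system is a plain band
table: an ordered set of parameter rules, each rule a list of
(band predicate -> points) entries with points in {1, 2, 3}.  A value
that matches no band scores 0; a value that matches several bands (the
printed tables overlap at some boundaries) takes the *maximum* points,
the safety-first reading of an escalation chart.

The tables are data, not code: they round-trip through a YAML document
(one document per system, one entry per band), and the packaged
``tables/meows.yaml`` / ``tables/ews.yaml`` files are bit-identical to
the built-in constructors.

Both a per-observation scorer (:func:`score_observation`) and a
vectorised scorer over a long-format cohort table
(:func:`score_table`) are provided; the two are required to agree and
the test suite checks them against each other and against a
brute-force oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AVPU_LEVELS",
    "PARAMETERS",
    "NUMERIC_PARAMETERS",
    "ScoreBand",
    "ParameterRule",
    "ScoringSystem",
    "VitalsObservation",
    "ObservationScore",
    "ValidationIssue",
    "InvalidObservationError",
    "EmptyObservationError",
    "between",
    "below",
    "above",
    "at_least",
    "when_true",
    "one_of",
    "build_meows_system",
    "build_ews_system",
    "MEOWS",
    "EWS",
    "score_parameter",
    "score_observation",
    "score_table",
    "validate_observation",
    "band_gaps",
    "system_to_dict",
    "system_from_dict",
    "dump_system",
    "load_system",
    "load_packaged_system",
]

#: Consciousness levels on the AVPU scale.
AVPU_LEVELS = ("A", "V", "P", "U")

#: The nine monitored physiological parameters, in chart order.
PARAMETERS = (
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

NUMERIC_PARAMETERS = (
    "resp_rate",
    "spo2",
    "temperature",
    "sbp",
    "dbp",
    "heart_rate",
    "vas_pain",
)

#: Parameters whose physical value must be strictly positive when present.
_STRICTLY_POSITIVE = ("resp_rate", "temperature", "sbp", "dbp", "heart_rate")

_INF = float("inf")


class InvalidObservationError(ValueError):
    """A vital-sign value is non-finite or of the wrong type."""


class EmptyObservationError(ValueError):
    """Every parameter a system scores is missing from the observation."""


# ---------------------------------------------------------------------------
# Band predicates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreBand:
    """One cell of a scoring table: a predicate and the points it awards.

    ``kind`` is one of ``"interval"`` (numeric range with inclusive /
    exclusive ends; open-ended bounds use +/-inf), ``"flag"`` (matches a
    truthy boolean) or ``"members"`` (membership in a set of levels).
    """

    points: int
    kind: str = "interval"
    lo: float = -_INF
    hi: float = _INF
    lo_incl: bool = True
    hi_incl: bool = True
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.points not in (1, 2, 3):
            raise ValueError(f"band points must be in 1..3, got {self.points}")
        if self.kind == "interval" and self.lo > self.hi:
            raise ValueError(f"empty interval [{self.lo}, {self.hi}]")
        if self.kind not in ("interval", "flag", "members"):
            raise ValueError(f"unknown band kind {self.kind!r}")

    def matches(self, value: Any) -> bool:
        if self.kind == "flag":
            return bool(value)
        if self.kind == "members":
            return value in self.members
        lo_ok = value > self.lo or (self.lo_incl and value == self.lo)
        hi_ok = value < self.hi or (self.hi_incl and value == self.hi)
        return bool(lo_ok and hi_ok)


def between(lo: float, hi: float, points: int) -> ScoreBand:
    """Closed numeric band ``[lo, hi]`` (the printed ``a-b`` notation)."""
    return ScoreBand(points, "interval", float(lo), float(hi))


def below(x: float, points: int) -> ScoreBand:
    """Strict lower band ``< x``."""
    return ScoreBand(points, "interval", -_INF, float(x), hi_incl=False)


def above(x: float, points: int) -> ScoreBand:
    """Strict upper band ``> x``."""
    return ScoreBand(points, "interval", float(x), _INF, lo_incl=False)


def at_least(x: float, points: int) -> ScoreBand:
    """Closed upper band ``>= x``."""
    return ScoreBand(points, "interval", float(x), _INF)


def when_true(points: int) -> ScoreBand:
    """Boolean-flag band (e.g. oxygen supplementation in use)."""
    return ScoreBand(points, "flag")


def one_of(members: Iterable[str], points: int) -> ScoreBand:
    """Enum-membership band (e.g. AVPU in {V, P, U})."""
    return ScoreBand(points, "members", members=frozenset(members))


# ---------------------------------------------------------------------------
# Rules and systems
# ---------------------------------------------------------------------------


def _is_missing(value: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


@dataclass(frozen=True)
class ParameterRule:
    """The scoring row for one physiological parameter."""

    parameter: str
    bands: tuple[ScoreBand, ...]

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        object.__setattr__(self, "bands", tuple(self.bands))

    def score(self, value: Any) -> int:
        """Points for ``value``: max over matching bands, 0 if none match.

        Missing values (None/NaN) score 0.  Non-finite numeric values are
        rejected.
        """
        if _is_missing(value):
            return 0
        if self.parameter in NUMERIC_PARAMETERS:
            try:
                value = float(value)
            except (TypeError, ValueError) as exc:
                raise InvalidObservationError(
                    f"{self.parameter}: non-numeric value {value!r}"
                ) from exc
            if not math.isfinite(value):
                raise InvalidObservationError(
                    f"{self.parameter}: non-finite value {value!r}"
                )
        return max((b.points for b in self.bands if b.matches(value)), default=0)

    @property
    def max_points(self) -> int:
        return max(b.points for b in self.bands)


@dataclass(frozen=True)
class ScoringSystem:
    """An ordered set of parameter rules (one early-warning score chart)."""

    name: str
    rules: tuple[ParameterRule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        params = [r.parameter for r in self.rules]
        if len(set(params)) != len(params):
            raise ValueError(f"{self.name}: a parameter appears in two rules")

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(r.parameter for r in self.rules)

    def rule_for(self, parameter: str) -> ParameterRule:
        for r in self.rules:
            if r.parameter == parameter:
                return r
        raise KeyError(parameter)

    def score(self, obs: "VitalsObservation") -> "ObservationScore":
        per: dict[str, int] = {}
        n_missing = 0
        for rule in self.rules:
            value = getattr(obs, rule.parameter)
            if _is_missing(value):
                n_missing += 1
                per[rule.parameter] = 0
            else:
                per[rule.parameter] = rule.score(value)
        if n_missing == len(self.rules):
            raise EmptyObservationError(
                f"{self.name}: all {len(self.rules)} scored parameters missing"
            )
        values = per.values()
        return ObservationScore(
            system=self.name,
            per_parameter=per,
            total=sum(values),
            max_single=max(values),
            n_missing=n_missing,
        )


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VitalsObservation:
    """One timestamped set of the nine monitored parameters.

    ``timestamp`` is hours since HDU admission.  Every physiological field
    is individually optional; a missing field scores 0 under either system.
    """

    woman_id: str
    timestamp: float
    resp_rate: float | None = None
    spo2: float | None = None
    o2_supplement: bool | None = None
    temperature: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    heart_rate: float | None = None
    avpu: str | None = None
    vas_pain: float | None = None


@dataclass(frozen=True)
class ObservationScore:
    """Per-parameter points, their total, the single worst value, and the
    number of parameters that were missing (each contributing 0)."""

    system: str
    per_parameter: Mapping[str, int]
    total: int
    max_single: int
    n_missing: int


def score_parameter(value: Any, rule: ParameterRule) -> int:
    """Points awarded to ``value`` under one parameter rule."""
    return rule.score(value)


def score_observation(obs: VitalsObservation, system: ScoringSystem) -> ObservationScore:
    """Score a single observation under ``system``."""
    return system.score(obs)


# ---------------------------------------------------------------------------
# Vectorised scoring over a long-format cohort table
# ---------------------------------------------------------------------------


def score_table(frame: pd.DataFrame, system: ScoringSystem) -> pd.DataFrame:
    """Score every row of a long-format cohort table.

    ``frame`` must carry one column per parameter the system scores
    (missing values as NaN/None; AVPU as letters; booleans as 0/1/bool).
    Returns a DataFrame indexed like ``frame`` with one points column per
    parameter plus ``total``, ``max_single`` and ``n_missing``.  Agrees
    exactly with :func:`score_observation` row by row.
    """
    n = len(frame)
    out: dict[str, np.ndarray] = {}
    missing_count = np.zeros(n, dtype=np.int64)
    for rule in system.rules:
        col = frame[rule.parameter]
        points = np.zeros(n, dtype=np.int64)
        if rule.parameter == "avpu":
            values = col.to_numpy(dtype=object)
            missing = np.array([_is_missing(v) for v in values], dtype=bool)
            for band in rule.bands:
                mask = np.isin(values, list(band.members)) & ~missing
                points = np.maximum(points, np.where(mask, band.points, 0))
        elif rule.parameter == "o2_supplement":
            values = col.to_numpy(dtype=object)
            missing = np.array([_is_missing(v) for v in values], dtype=bool)
            truthy = np.array([bool(v) for v in values], dtype=bool) & ~missing
            for band in rule.bands:
                points = np.maximum(points, np.where(truthy, band.points, 0))
        else:
            values = col.to_numpy(dtype=float)
            missing = np.isnan(values)
            if np.isinf(values).any():
                raise InvalidObservationError(
                    f"{rule.parameter}: non-finite value in table"
                )
            for band in rule.bands:
                lo_ok = values >= band.lo if band.lo_incl else values > band.lo
                hi_ok = values <= band.hi if band.hi_incl else values < band.hi
                mask = lo_ok & hi_ok & ~missing
                points = np.maximum(points, np.where(mask, band.points, 0))
        out[rule.parameter] = points
        missing_count += missing.astype(np.int64)
    if (missing_count == len(system.rules)).any():
        raise EmptyObservationError(
            f"{system.name}: some rows have every scored parameter missing"
        )
    result = pd.DataFrame(out, index=frame.index)
    stacked = np.column_stack(list(out.values()))
    result["total"] = stacked.sum(axis=1)
    result["max_single"] = stacked.max(axis=1)
    result["n_missing"] = missing_count
    return result


# ---------------------------------------------------------------------------
# Band-gap analysis and observation validation
# ---------------------------------------------------------------------------


def _covered_intervals(rule: ParameterRule) -> list[tuple[float, float, bool, bool]]:
    """Merged union of the rule's numeric bands as (lo, hi, lo_incl, hi_incl)."""
    ivals = sorted(
        (b.lo, b.hi, b.lo_incl, b.hi_incl)
        for b in rule.bands
        if b.kind == "interval"
    )
    merged: list[list] = []
    for lo, hi, li, hi_i in ivals:
        if merged:
            plo, phi, pli, phi_i = merged[-1]
            touching = lo < phi or (lo == phi and (li or phi_i))
            if touching:
                if hi > phi or (hi == phi and hi_i):
                    merged[-1][1], merged[-1][3] = hi, hi_i
                continue
        merged.append([lo, hi, li, hi_i])
    return [tuple(m) for m in merged]


@lru_cache(maxsize=None)
def band_gaps(rule: ParameterRule) -> tuple[tuple[float, float], ...]:
    """Suspicious uncovered intervals in a numeric rule's band ladder.

    The bounded uncovered intervals between the rule's covered regions are
    computed; the single widest one is taken to be the implicit "normal"
    zone of the chart (the printed tables have no explicit 0-point column)
    and the remainder are reported as gaps — discontinuities in the printed
    escalation ladder where a value silently scores 0 (e.g. a heart rate of
    exactly 40 under the general EWS, which falls between "< 40" and
    "41-50").  Returned as closed-span (lo, hi) pairs: a value v lies in
    the gap iff lo <= v <= hi and it matches no band.
    """
    covered = _covered_intervals(rule)
    if len(covered) < 2:
        return ()
    holes: list[tuple[float, float]] = []
    for (_, phi, _, _), (nlo, _, _, _) in zip(covered, covered[1:]):
        holes.append((phi, nlo))
    widest = max(range(len(holes)), key=lambda i: holes[i][1] - holes[i][0])
    return tuple(h for i, h in enumerate(holes) if i != widest)


@dataclass(frozen=True)
class ValidationIssue:
    field: str
    kind: str  # "range" | "non_finite" | "type" | "band_gap"
    message: str


def validate_observation(
    obs: VitalsObservation, system: ScoringSystem | None = None
) -> list[ValidationIssue]:
    """Check an observation against the type invariants.

    Returns range violations, non-finite numbers and type problems; when a
    ``system`` is supplied, values that fall inside a documented band gap
    of that system's tables are additionally surfaced as ``band_gap``
    notes (they still score 0 — gaps are honoured literally, never
    silently extended).  An empty list means the observation is clean.
    """
    issues: list[ValidationIssue] = []
    for name in NUMERIC_PARAMETERS:
        value = getattr(obs, name)
        if _is_missing(value):
            continue
        try:
            value = float(value)
        except (TypeError, ValueError):
            issues.append(ValidationIssue(name, "type", f"{name}={value!r} is not numeric"))
            continue
        if not math.isfinite(value):
            issues.append(ValidationIssue(name, "non_finite", f"{name}={value!r}"))
            continue
        if name == "spo2" and not 0.0 <= value <= 100.0:
            issues.append(ValidationIssue(name, "range", f"spo2={value} outside 0-100"))
        elif name == "vas_pain" and not 0.0 <= value <= 10.0:
            issues.append(ValidationIssue(name, "range", f"vas_pain={value} outside 0-10"))
        elif name in _STRICTLY_POSITIVE and value <= 0.0:
            issues.append(ValidationIssue(name, "range", f"{name}={value} not positive"))
    if obs.avpu is not None and obs.avpu not in AVPU_LEVELS:
        issues.append(
            ValidationIssue("avpu", "range", f"avpu={obs.avpu!r} not one of {AVPU_LEVELS}")
        )
    if obs.o2_supplement is not None and not isinstance(obs.o2_supplement, (bool, np.bool_, int)):
        issues.append(
            ValidationIssue("o2_supplement", "type", f"o2_supplement={obs.o2_supplement!r} not boolean")
        )
    if system is not None and not any(i.kind in ("range", "non_finite", "type") for i in issues):
        for rule in system.rules:
            if rule.parameter not in NUMERIC_PARAMETERS:
                continue
            value = getattr(obs, rule.parameter)
            if _is_missing(value):
                continue
            value = float(value)
            if rule.score(value) == 0:
                for lo, hi in band_gaps(rule):
                    if lo <= value <= hi:
                        issues.append(
                            ValidationIssue(
                                rule.parameter,
                                "band_gap",
                                f"{rule.parameter}={value} falls in the unscored gap "
                                f"[{lo}, {hi}] of the {system.name} table",
                            )
                        )
                        break
    return issues


# ---------------------------------------------------------------------------
# Built-in systems
# ---------------------------------------------------------------------------


def build_meows_system() -> ScoringSystem:
    """The nine-rule obstetric MEOWS band table, exactly as charted.

    Note the deliberate printed overlaps at band boundaries (systolic 150
    and 160, heart rate 120/130 and 50/60, pain score 7): a value on such
    a boundary takes the higher points.
    """
    return ScoringSystem(
        "MEOWS",
        (
            ParameterRule("resp_rate", (between(21, 25, 2), below(12, 3), above(25, 3))),
            ParameterRule("spo2", (between(92, 95, 2), below(92, 3))),
            ParameterRule("o2_supplement", (when_true(2),)),
            ParameterRule(
                "temperature", (between(37.3, 37.7, 2), above(37.7, 3), below(36.0, 3))
            ),
            ParameterRule(
                "sbp",
                (between(140, 150, 1), between(150, 160, 2), above(160, 3), below(90, 3)),
            ),
            ParameterRule(
                "dbp", (between(90, 100, 1), between(100, 110, 2), above(110, 3))
            ),
            ParameterRule(
                "heart_rate",
                (
                    between(110, 120, 1),
                    between(120, 130, 2),
                    between(50, 60, 2),
                    above(130, 3),
                    below(50, 3),
                ),
            ),
            ParameterRule("avpu", (one_of(("V", "P", "U"), 3),)),
            ParameterRule("vas_pain", (between(4, 7, 2), at_least(7, 3))),
        ),
    )


def build_ews_system() -> ScoringSystem:
    """The five-rule general adult EWS band table, exactly as charted.

    The printed table is honoured literally, including its discontinuities
    (a heart rate of exactly 40 or 130 matches no band and scores 0) and
    its empty 3-point temperature column.
    """
    return ScoringSystem(
        "EWS",
        (
            ParameterRule(
                "heart_rate",
                (
                    between(41, 50, 1),
                    between(101, 110, 1),
                    between(111, 129, 2),
                    below(40, 2),
                    above(130, 3),
                ),
            ),
            ParameterRule(
                "sbp",
                (between(81, 100, 1), between(71, 80, 2), above(200, 2), below(70, 3)),
            ),
            ParameterRule(
                "resp_rate",
                (between(15, 20, 1), between(21, 29, 2), below(8, 2), above(30, 3)),
            ),
            ParameterRule(
                "temperature", (between(35.1, 36.5, 1), above(37.5, 1), below(35, 2))
            ),
            ParameterRule(
                "avpu",
                (one_of(("V",), 1), one_of(("P",), 2), one_of(("U",), 3)),
            ),
        ),
    )


#: Module-level singletons of the two built-in systems.
MEOWS = build_meows_system()
EWS = build_ews_system()


# ---------------------------------------------------------------------------
# YAML serialisation (the engine is data-driven)
# ---------------------------------------------------------------------------


def _band_to_dict(band: ScoreBand) -> dict:
    d: dict[str, Any] = {"points": band.points}
    if band.kind == "flag":
        d["when"] = True
    elif band.kind == "members":
        d["any_of"] = sorted(band.members)
    else:
        lo_finite = math.isfinite(band.lo)
        hi_finite = math.isfinite(band.hi)
        if lo_finite and hi_finite:
            d["from"] = band.lo
            d["to"] = band.hi
        elif hi_finite:
            d["below" if not band.hi_incl else "at_most"] = band.hi
        else:
            d["above" if not band.lo_incl else "at_least"] = band.lo
    return d


def _band_from_dict(d: Mapping[str, Any]) -> ScoreBand:
    points = int(d["points"])
    if d.get("when"):
        return when_true(points)
    if "any_of" in d:
        return one_of(d["any_of"], points)
    if "from" in d:
        return between(float(d["from"]), float(d["to"]), points)
    if "below" in d:
        return below(float(d["below"]), points)
    if "at_most" in d:
        return ScoreBand(points, "interval", -_INF, float(d["at_most"]))
    if "above" in d:
        return above(float(d["above"]), points)
    if "at_least" in d:
        return at_least(float(d["at_least"]), points)
    raise ValueError(f"unrecognised band entry: {dict(d)!r}")


def system_to_dict(system: ScoringSystem) -> dict:
    return {
        "name": system.name,
        "rules": [
            {"parameter": r.parameter, "bands": [_band_to_dict(b) for b in r.bands]}
            for r in system.rules
        ],
    }


def system_from_dict(d: Mapping[str, Any]) -> ScoringSystem:
    return ScoringSystem(
        str(d["name"]),
        tuple(
            ParameterRule(
                r["parameter"], tuple(_band_from_dict(b) for b in r["bands"])
            )
            for r in d["rules"]
        ),
    )


def dump_system(system: ScoringSystem, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(system_to_dict(system), fh, sort_keys=False)


def load_system(path) -> ScoringSystem:
    with open(path) as fh:
        return system_from_dict(yaml.safe_load(fh))


def load_packaged_system(name: str) -> ScoringSystem:
    """Load one of the shipped table files ("meows" or "ews")."""
    text = (resources.files("meows") / "tables" / f"{name.lower()}.yaml").read_text()
    return system_from_dict(yaml.safe_load(text))
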