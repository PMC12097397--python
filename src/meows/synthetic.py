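"""Seeded synthetic postpartum HDU cohorts.

The generator emulates the structure of the validation cohort: 723
postpartum women monitored every 4 h for 48 h, 24 of them (3.3%) with
adjudicated severe maternal morbidity, whose causes split as
hypertensive 13/24, hemorrhage 8/24, pulmonary 2/24 and anesthesia
1/24.  Each woman is assigned a target worst-MEOWS stratum drawn from
her group's category-frequency table — (14, 8, 2, 0)/24 for morbid
women over (red, yellow, green, none) and (6, 259, 294, 140)/699 for
non-morbid women — and her observations are then *constructed to
realise exactly that stratum*: baseline observations are sampled from
ranges that score 0 under MEOWS, and a single "peak" observation is
composed from the scoring table itself (parameter bands chosen to sum
to the stratum's score window, with per-parameter propensities that
reflect the morbidity subtype) and verified by re-scoring with the real
engine.  The general-EWS stratum of a generated woman is whatever the
EWS table yields on those vitals; only the MEOWS margins are calibrated
(the true joint MEOWS/EWS distribution is not identifiable from the
published margins).

Covariates are sampled to match the published per-group medians and
quartiles (split half-normal quantile draws; categorical mixtures at
the published proportions).

Everything is driven by a single ``numpy`` Generator, so a seed plus a
config reproduces a cohort byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .scoring import (
    MEOWS,
    ParameterRule,
    ScoringSystem,
    VitalsObservation,
)
from .triage import Covariates, StayRecord, TriageCategory, meows_triage

__all__ = [
    "SUBTYPES",
    "OutcomeProfile",
    "PROFILES",
    "SyntheticConfig",
    "GenerationError",
    "generate_cohort",
    "generate_cohort_frame",
    "sample_observation_for_category",
    "sample_covariates",
]


class GenerationError(RuntimeError):
    """The rejection budget was exhausted for an infeasible target."""


SUBTYPES = ("hypertensive", "hemorrhage", "pulmonary", "anesthesia")

_CATEGORY_NAMES = ("red", "yellow", "green", "none")
_NAME_TO_CATEGORY = {
    "red": TriageCategory.RED,
    "yellow": TriageCategory.YELLOW,
    "green": TriageCategory.GREEN,
    "none": TriageCategory.NONE,
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _default_subtype_mixture() -> dict[str, float]:
    return {
        "hypertensive": 13 / 24,
        "hemorrhage": 8 / 24,
        "pulmonary": 2 / 24,
        "anesthesia": 1 / 24,
    }


def _default_morbid_categories() -> dict[str, float]:
    return {"red": 14 / 24, "yellow": 8 / 24, "green": 2 / 24, "none": 0.0}


def _default_nonmorbid_categories() -> dict[str, float]:
    return {"red": 6 / 699, "yellow": 259 / 699, "green": 294 / 699, "none": 140 / 699}


def _default_ews_targets() -> dict[str, float]:
    # Best-effort calibration targets for the general-EWS margins; the
    # generator does not enforce them (only MEOWS strata are constructed).
    return {
        "ge2_morbid": 15 / 24,
        "ge2_nonmorbid": 238 / 699,
        "ge4_morbid": 2 / 24,
        "ge4_nonmorbid": 6 / 699,
    }


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic cohort generator.

    Defaults are the published cohort conditions: 723 women, 24/723
    prevalence, the published cause mixture, the canonical worst-stratum
    frequency tables, and a 4-hourly observation schedule over the 48 h
    minimum HDU stay (13 observations per woman).
    """

    n_women: int = 723
    prevalence: float = 24 / 723
    subtype_mixture: dict[str, float] = field(default_factory=_default_subtype_mixture)
    morbid_categories: dict[str, float] = field(default_factory=_default_morbid_categories)
    nonmorbid_categories: dict[str, float] = field(
        default_factory=_default_nonmorbid_categories
    )
    ews_targets: dict[str, float] = field(default_factory=_default_ews_targets)
    obs_interval_h: float = 4.0
    obs_duration_h: float = 48.0
    seed: int = 0
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        for name, mix in (
            ("subtype_mixture", self.subtype_mixture),
            ("morbid_categories", self.morbid_categories),
            ("nonmorbid_categories", self.nonmorbid_categories),
        ):
            values = list(mix.values())
            if any(not 0.0 <= v <= 1.0 for v in values):
                raise ValueError(f"{name}: probabilities must lie in [0, 1]")
            if abs(sum(values) - 1.0) > 1e-9:
                raise ValueError(f"{name}: mixture must sum to 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.n_women < 1:
            raise ValueError("n_women must be positive")

    @property
    def schedule(self) -> np.ndarray:
        """Observation times in hours since admission."""
        return np.arange(0.0, self.obs_duration_h + 1e-9, self.obs_interval_h)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SyntheticConfig":
        return cls(**dict(d))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Vital-sign profiles
# ---------------------------------------------------------------------------

#: Baseline (non-deteriorated) sampling ranges, chosen inside the MEOWS
#: zero-score region so a baseline observation always maps to the NONE
#: stratum: (mean, sd, lower clip, upper clip) of a clipped normal.
BASELINE_VITALS: Mapping[str, tuple[float, float, float, float]] = {
    "resp_rate": (14.0, 1.5, 12.0, 19.5),
    "spo2": (97.5, 1.0, 96.0, 100.0),
    "temperature": (36.9, 0.18, 36.6, 37.2),
    "sbp": (118.0, 10.0, 96.0, 138.0),
    "dbp": (74.0, 7.0, 62.0, 88.0),
    "heart_rate": (82.0, 9.0, 62.0, 104.0),
}

#: Baseline pain-score distribution (integers 0-3 score 0 under MEOWS).
BASELINE_VAS = ((0, 1, 2, 3), (0.45, 0.30, 0.15, 0.10))

#: Plausible physiological sampling range per numeric parameter; peak
#: values are drawn inside these limits.
PLAUSIBLE_RANGES: Mapping[str, tuple[float, float]] = {
    "resp_rate": (5.0, 45.0),
    "spo2": (78.0, 100.0),
    "temperature": (34.2, 40.0),
    "sbp": (62.0, 210.0),
    "dbp": (42.0, 135.0),
    "heart_rate": (36.0, 175.0),
}


@dataclass(frozen=True)
class OutcomeProfile:
    """Deterioration flavour of a morbidity subtype.

    ``weights`` are the relative propensities for each parameter to be
    the one that deteriorates; ``directions`` pick the abnormal side when
    a parameter has both a low and a high scoring region (a hemorrhage
    drops the systolic pressure, a hypertensive crisis raises it);
    ``avpu_weights`` weight the reduced-consciousness levels.  These are
    free calibration constants: they shape which vitals carry the score,
    never the score itself (the worst MEOWS stratum is constructed
    exactly and verified by re-scoring).
    """

    name: str
    weights: Mapping[str, float]
    directions: Mapping[str, str] = field(default_factory=dict)
    avpu_weights: Mapping[str, float] = field(
        default_factory=lambda: {"V": 0.6, "P": 0.3, "U": 0.1}
    )


PROFILES: Mapping[str, OutcomeProfile] = {
    "hypertensive": OutcomeProfile(
        "hypertensive",
        weights={
            "sbp": 6.0,
            "dbp": 4.0,
            "heart_rate": 1.0,
            "vas_pain": 1.0,
            "resp_rate": 0.5,
            "temperature": 0.5,
            "spo2": 0.3,
            "o2_supplement": 0.3,
            "avpu": 0.2,
        },
        directions={"sbp": "high", "dbp": "high", "heart_rate": "high"},
    ),
    "hemorrhage": OutcomeProfile(
        "hemorrhage",
        weights={
            "heart_rate": 5.0,
            "sbp": 3.0,
            "spo2": 2.0,
            "resp_rate": 1.5,
            "o2_supplement": 1.0,
            "vas_pain": 1.0,
            "temperature": 0.5,
            "avpu": 0.5,
            "dbp": 0.2,
        },
        directions={"heart_rate": "high", "sbp": "low", "temperature": "low"},
    ),
    "pulmonary": OutcomeProfile(
        "pulmonary",
        weights={
            "resp_rate": 5.0,
            "spo2": 4.0,
            "o2_supplement": 3.0,
            "heart_rate": 1.5,
            "temperature": 1.0,
            "vas_pain": 0.5,
            "sbp": 0.3,
            "avpu": 0.3,
            "dbp": 0.2,
        },
        directions={"resp_rate": "high", "heart_rate": "high", "temperature": "high"},
    ),
    "anesthesia": OutcomeProfile(
        "anesthesia",
        weights={
            "avpu": 4.0,
            "vas_pain": 4.0,
            "heart_rate": 1.0,
            "sbp": 1.0,
            "resp_rate": 1.0,
            "dbp": 0.5,
            "spo2": 0.5,
            "o2_supplement": 0.5,
            "temperature": 0.3,
        },
        directions={"resp_rate": "low", "sbp": "low"},
    ),
    # Benign postpartum deviations are dominated by transient hypertension
    # and pain, which the general adult EWS largely does not score; this
    # also keeps the generated EWS margins near their best-effort targets.
    "generic": OutcomeProfile(
        "generic",
        weights={
            "sbp": 3.0,
            "dbp": 2.5,
            "vas_pain": 2.0,
            "heart_rate": 1.2,
            "temperature": 1.0,
            "resp_rate": 0.6,
            "spo2": 0.5,
            "o2_supplement": 0.4,
            "avpu": 0.2,
        },
        directions={"sbp": "high", "dbp": "high", "heart_rate": "high"},
    ),
}


# ---------------------------------------------------------------------------
# Exact-score regions of the band tables
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _exact_regions(
    rule: ParameterRule, points: int, lo: float, hi: float
) -> tuple[tuple[float, float], ...]:
    """Open intervals inside [lo, hi] where ``rule`` scores exactly ``points``.

    Derived from the rule itself by scoring the midpoint of every
    elementary interval between band endpoints, so the generator can
    never drift out of sync with the scoring table.
    """
    cuts = {lo, hi}
    for band in rule.bands:
        if band.kind != "interval":
            continue
        for edge in (band.lo, band.hi):
            if math.isfinite(edge) and lo < edge < hi:
                cuts.add(float(edge))
    edges = sorted(cuts)
    regions = []
    for a, b in zip(edges, edges[1:]):
        if rule.score((a + b) / 2.0) == points:
            regions.append((a, b))
    return tuple(regions)


@lru_cache(maxsize=None)
def _discrete_levels(rule: ParameterRule, points: int, domain: tuple) -> tuple:
    return tuple(v for v in domain if rule.score(v) == points)


@lru_cache(maxsize=None)
def _available_points(system: ScoringSystem) -> dict[str, tuple[int, ...]]:
    """Achievable exact point values per parameter under ``system``."""
    out: dict[str, tuple[int, ...]] = {}
    for rule in system.rules:
        if rule.parameter == "o2_supplement":
            levels = tuple(sorted({b.points for b in rule.bands}))
        elif rule.parameter == "avpu":
            levels = tuple(
                sorted(
                    {p for p in (1, 2, 3) if _discrete_levels(rule, p, ("V", "P", "U"))}
                )
            )
        elif rule.parameter == "vas_pain":
            levels = tuple(
                sorted(
                    {p for p in (1, 2, 3) if _discrete_levels(rule, p, tuple(range(11)))}
                )
            )
        else:
            span = PLAUSIBLE_RANGES[rule.parameter]
            levels = tuple(
                sorted({p for p in (1, 2, 3) if _exact_regions(rule, p, *span)})
            )
        out[rule.parameter] = levels
    return out


# ---------------------------------------------------------------------------
# Peak-observation composition
# ---------------------------------------------------------------------------


def _weighted_order(params: Sequence[str], weights: Mapping[str, float], rng) -> list[str]:
    # Gumbel trick: weighted sampling without replacement.
    w = np.array([max(weights.get(p, 0.0), 1e-9) for p in params])
    keys = np.log(w) + rng.gumbel(size=len(params))
    return [params[i] for i in np.argsort(-keys)]


def _compose_parts(
    category: TriageCategory,
    rng: np.random.Generator,
    profile: OutcomeProfile,
    system: ScoringSystem,
) -> dict[str, int] | None:
    """Choose (parameter -> points) parts realising ``category``.

    GREEN composes 1-4 points from 1- and 2-point bands; YELLOW either
    totals 5-6 without any 3 or hangs extras (<= 3 points) off a single
    3-point value; RED totals at least 7.  Returns None when a greedy
    pass fails to hit the target total exactly (the caller retries).
    """
    available = _available_points(system)
    if category is TriageCategory.NONE:
        return {}
    must_three = False
    if category is TriageCategory.GREEN:
        target = int(rng.choice([1, 2, 3, 4], p=[0.30, 0.35, 0.20, 0.15]))
        cap = 2
    elif category is TriageCategory.YELLOW:
        if rng.random() < 0.5:
            target = int(rng.choice([5, 6]))
            cap = 2
        else:
            target = 3 + int(rng.choice([0, 1, 2, 3], p=[0.50, 0.25, 0.15, 0.10]))
            cap = 2
            must_three = True
    else:  # RED
        target = int(rng.choice([7, 8, 9, 10], p=[0.45, 0.30, 0.15, 0.10]))
        cap = 3

    parts: dict[str, int] = {}
    remaining = target
    params = list(available)
    if must_three:
        three_capable = [p for p in params if 3 in available[p]]
        first = _weighted_order(three_capable, profile.weights, rng)[0]
        parts[first] = 3
        remaining -= 3
    order = _weighted_order([p for p in params if p not in parts], profile.weights, rng)
    for param in order:
        if remaining == 0:
            break
        usable = [p for p in available[param] if p <= min(cap, remaining)]
        if not usable:
            continue
        pick = max(usable)
        parts[param] = pick
        remaining -= pick
    return parts if remaining == 0 else None


def _sample_part_value(
    param: str,
    points: int,
    rng: np.random.Generator,
    profile: OutcomeProfile,
    system: ScoringSystem,
):
    """A concrete parameter value scoring exactly ``points``."""
    rule = system.rule_for(param)
    if param == "o2_supplement":
        return True
    if param == "avpu":
        levels = _discrete_levels(rule, points, ("V", "P", "U"))
        w = np.array([profile.avpu_weights.get(l, 0.1) for l in levels])
        return str(rng.choice(levels, p=w / w.sum()))
    if param == "vas_pain":
        return float(rng.choice(_discrete_levels(rule, points, tuple(range(11)))))
    regions = _exact_regions(rule, points, *PLAUSIBLE_RANGES[param])
    if not regions:
        raise GenerationError(f"{param}: no region scores exactly {points}")
    base_lo, base_hi = None, None
    if param in BASELINE_VITALS:
        _, _, base_lo, base_hi = BASELINE_VITALS[param]
    direction = profile.directions.get(param)
    preferred = regions
    if direction == "high" and base_hi is not None:
        high = tuple(r for r in regions if r[0] >= base_hi)
        preferred = high or regions
    elif direction == "low" and base_lo is not None:
        low = tuple(r for r in regions if r[1] <= base_lo)
        preferred = low or regions
    widths = np.array([b - a for a, b in preferred])
    a, b = preferred[rng.choice(len(preferred), p=widths / widths.sum())]
    return round(float(rng.uniform(a, b)), _PRECISION[param])


def _baseline_values(rng: np.random.Generator, size: int) -> dict[str, np.ndarray]:
    """Vectorised baseline vitals guaranteed to score 0 under MEOWS."""
    out: dict[str, np.ndarray] = {}
    for param, (mean, sd, lo, hi) in BASELINE_VITALS.items():
        out[param] = np.round(np.clip(rng.normal(mean, sd, size), lo, hi), _PRECISION[param])
    values, probs = BASELINE_VAS
    out["vas_pain"] = rng.choice(values, size=size, p=probs).astype(float)
    out["o2_supplement"] = np.zeros(size, dtype=bool)
    out["avpu"] = np.full(size, "A", dtype=object)
    return out


def sample_observation_for_category(
    target: TriageCategory,
    profile: OutcomeProfile | str,
    rng: np.random.Generator | int,
    system: ScoringSystem = MEOWS,
    woman_id: str = "synthetic",
    timestamp: float = 0.0,
    max_attempts: int = 1000,
) -> VitalsObservation:
    """One observation whose MEOWS triage equals ``target`` exactly.

    The observation is composed from the band table (see
    :func:`_compose_parts`) and then verified by re-scoring with the real
    engine; a failed verification is rejected and retried.
    """
    if isinstance(profile, str):
        profile = PROFILES[profile]
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    target = TriageCategory(target)
    for _ in range(max_attempts):
        parts = _compose_parts(target, rng, profile, system)
        if parts is None:
            continue
        base = _baseline_values(rng, 1)
        values = {k: v[0] for k, v in base.items()}
        for param, points in parts.items():
            values[param] = _sample_part_value(param, points, rng, profile, system)
        obs = VitalsObservation(woman_id=woman_id, timestamp=timestamp, **values)
        if meows_triage(system.score(obs)) is target:
            return obs
    raise GenerationError(
        f"could not realise MEOWS stratum {target.name} in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

# (median, q1, q3, clip_lo, clip_hi) of the published per-group summaries.
_COVARIATE_QUANTILES = {
    False: {  # without severe maternal morbidity
        "age": (32.0, 28.0, 35.0, 16.0, 52.0),
        "bmi_prepregnancy": (23.9, 21.4, 27.5, 15.0, 55.0),
        "bmi_delivery": (29.2, 26.4, 32.7, 17.0, 60.0),
        "gestational_age": (39.1, 38.0, 40.0, 23.0, 42.5),
        "blood_loss_ml": (400.0, 300.0, 500.0, 50.0, 4000.0),
    },
    True: {  # with severe maternal morbidity
        "age": (30.5, 28.0, 33.5, 16.0, 52.0),
        "bmi_prepregnancy": (23.6, 21.3, 28.8, 15.0, 55.0),
        "bmi_delivery": (30.1, 25.9, 35.7, 17.0, 60.0),
        "gestational_age": (36.8, 31.5, 38.5, 23.0, 42.5),
        "blood_loss_ml": (500.0, 300.0, 1630.0, 50.0, 4000.0),
    },
}

_NULLIPARITY_P = {False: 367 / 699, True: 17 / 24}
_TWIN_P = {False: 31 / 699, True: 2 / 24}

_DELIVERY_MODES = ("vaginal", "planned_cesarean", "emergency_cesarean", "operative_vaginal")
_DELIVERY_P = {
    False: (117 / 699, 252 / 699, 321 / 699, 9 / 699),
    True: (5 / 24, 3 / 24, 16 / 24, 0.0),
}

# Days in HDU: discrete distributions with the published medians (2 vs 3)
# and plausible right tails over the published ranges (1-11 vs 2-10).
_DAYS_DIST = {
    False: (
        (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11),
        (0.10, 0.70, 0.10, 0.05, 0.02, 0.01, 0.008, 0.005, 0.003, 0.002, 0.002),
    ),
    True: (
        (2, 3, 4, 5, 6, 7, 8, 9, 10),
        (0.20, 0.45, 0.20, 0.06, 0.04, 0.02, 0.015, 0.010, 0.005),
    ),
}

#: Chart recording precision (decimal places) per numeric vital; values
#: are rounded to this precision *before* score verification, so the
#: emitted table scores identically to the verified observations.
_PRECISION = {
    "resp_rate": 1,
    "spo2": 1,
    "temperature": 2,
    "sbp": 1,
    "dbp": 1,
    "heart_rate": 1,
}

_Z_Q3 = 0.6744897501960817  # 75th percentile of the standard normal


def _split_half_normal(
    rng: np.random.Generator,
    size: int,
    median: float,
    q1: float,
    q3: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Quantile-matched asymmetric draws: exact median and quartiles.

    With probability 1/2 the draw is ``median - |Z| * (median-q1)/z75``,
    otherwise ``median + |Z| * (q3-median)/z75``; clipped to [lo, hi].
    """
    z = np.abs(rng.standard_normal(size))
    upper = rng.random(size) < 0.5
    sd_lo = (median - q1) / _Z_Q3
    sd_hi = (q3 - median) / _Z_Q3
    x = np.where(upper, median + z * sd_hi, median - z * sd_lo)
    return np.clip(x, lo, hi)


def _covariate_arrays(
    morbid: bool, rng: np.random.Generator, size: int
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for name, (med, q1, q3, lo, hi) in _COVARIATE_QUANTILES[morbid].items():
        out[name] = np.round(_split_half_normal(rng, size, med, q1, q3, lo, hi), 1)
    out["nulliparous"] = rng.random(size) < _NULLIPARITY_P[morbid]
    out["twin"] = rng.random(size) < _TWIN_P[morbid]
    out["delivery_mode"] = rng.choice(_DELIVERY_MODES, size=size, p=_DELIVERY_P[morbid])
    days, probs = _DAYS_DIST[morbid]
    out["days_in_hdu"] = rng.choice(days, size=size, p=probs).astype(float)
    return out


def sample_covariates(
    morbid: bool, rng: np.random.Generator | int, size: int | None = None
):
    """Covariates for one woman (or arrays for ``size`` women).

    At large n the sample medians approximate the published per-group
    medians (e.g. gestational age 39.1 weeks without vs 36.8 weeks with
    severe morbidity); categorical mixtures follow the published
    proportions.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    arrays = _covariate_arrays(bool(morbid), rng, 1 if size is None else size)
    if size is not None:
        return arrays
    return Covariates(
        age=float(arrays["age"][0]),
        bmi_prepregnancy=float(arrays["bmi_prepregnancy"][0]),
        bmi_delivery=float(arrays["bmi_delivery"][0]),
        gestational_age=float(arrays["gestational_age"][0]),
        nulliparous=bool(arrays["nulliparous"][0]),
        twin=bool(arrays["twin"][0]),
        delivery_mode=str(arrays["delivery_mode"][0]),
        blood_loss_ml=float(arrays["blood_loss_ml"][0]),
        days_in_hdu=float(arrays["days_in_hdu"][0]),
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort_frame(
    config: SyntheticConfig | None = None,
    seed: int | None = None,
    with_assignments: bool = False,
):
    """Generate a cohort as a long-format table (one row per observation).

    ``seed`` overrides ``config.seed``.  The morbid count is fixed at
    ``round(n_women * prevalence)`` (the emulated study cohort has a fixed
    composition) and assigned to shuffled positions.  Returns the frame,
    or ``(frame, assignments)`` when ``with_assignments`` is true, where
    ``assignments`` records each woman's group, subtype, target stratum
    and peak-observation slot.
    """
    from . import io as _io  # local import to avoid a cycle

    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else int(seed))
    n = config.n_women
    n_morbid = int(round(n * config.prevalence))
    morbid = np.zeros(n, dtype=bool)
    if n_morbid:
        morbid[rng.choice(n, size=n_morbid, replace=False)] = True

    subtype = np.full(n, "generic", dtype=object)
    if n_morbid:
        subtype[morbid] = rng.choice(
            list(config.subtype_mixture),
            size=n_morbid,
            p=list(config.subtype_mixture.values()),
        )

    category = np.empty(n, dtype=object)
    for is_morbid, table in (
        (True, config.morbid_categories),
        (False, config.nonmorbid_categories),
    ):
        mask = morbid == is_morbid
        if mask.any():
            category[mask] = rng.choice(
                _CATEGORY_NAMES,
                size=int(mask.sum()),
                p=[table[c] for c in _CATEGORY_NAMES],
            )

    times = config.schedule
    n_obs = len(times)
    total_rows = n * n_obs
    vitals = _baseline_values(rng, total_rows)
    peak_slot = rng.integers(0, n_obs, size=n)

    # Compose and verify the peak observation of every non-NONE stay.
    for i in range(n):
        cat = _NAME_TO_CATEGORY[category[i]]
        if cat is TriageCategory.NONE:
            continue
        profile = PROFILES[subtype[i]]
        row = i * n_obs + int(peak_slot[i])
        realised = False
        for _ in range(config.max_attempts):
            parts = _compose_parts(cat, rng, profile, MEOWS)
            if parts is None:
                continue
            values = {k: vitals[k][row] for k in vitals}
            for param, points in parts.items():
                values[param] = _sample_part_value(param, points, rng, profile, MEOWS)
            obs = VitalsObservation(woman_id="peak", timestamp=0.0, **values)
            if meows_triage(MEOWS.score(obs)) is cat:
                for param, value in values.items():
                    vitals[param][row] = value
                realised = True
                break
        if not realised:
            raise GenerationError(
                f"woman {i}: stratum {cat.name} not realised in "
                f"{config.max_attempts} attempts"
            )

    woman_ids = np.array([f"W{i:04d}" for i in range(n)], dtype=object)
    frame = pd.DataFrame(
        {
            "woman_id": np.repeat(woman_ids, n_obs),
            "timestamp": np.tile(times, n),
            "resp_rate": vitals["resp_rate"],
            "spo2": vitals["spo2"],
            "o2_supplement": vitals["o2_supplement"],
            "temperature": vitals["temperature"],
            "sbp": vitals["sbp"],
            "dbp": vitals["dbp"],
            "heart_rate": vitals["heart_rate"],
            "avpu": vitals["avpu"],
            "vas_pain": vitals["vas_pain"],
            "morbidity": np.repeat(morbid, n_obs),
        }
    )
    covs = {k: np.empty(n, dtype=object) for k in _io.COVARIATE_COLUMNS}
    for is_morbid in (False, True):
        mask = morbid == is_morbid
        if not mask.any():
            continue
        arrays = _covariate_arrays(is_morbid, rng, int(mask.sum()))
        for k, arr in arrays.items():
            covs[k][mask] = arr
    for k in _io.COVARIATE_COLUMNS:
        frame[k] = np.repeat(covs[k], n_obs)

    if with_assignments:
        assignments = pd.DataFrame(
            {
                "woman_id": woman_ids,
                "morbidity": morbid,
                "subtype": subtype,
                "target_category": category,
                "peak_slot": peak_slot,
            }
        )
        return frame, assignments
    return frame


def generate_cohort(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> list[StayRecord]:
    """Generate a cohort as a list of :class:`StayRecord`."""
    from . import io as _io

    return _io.frame_to_stays(generate_cohort_frame(config, seed))
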