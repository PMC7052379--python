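"""Synthetic cohort generator emulating the two-championship blood-test dataset.

The real per-athlete dataset is not public, so every downstream stage is
exercised on generated cohorts that reproduce the study's structure:

* covariate composition of the two events (sex, age class, continent,
  endurance discipline share, altitude allocation, sampling time);
* ethnicity imposed per continent;
* score-scale covariate effects materialized on the hematological variables;
* a doped/clean mixture with configurable per-stratum prevalence, the doped
  effect mimicking low-dose rhEPO (HGB/HCT/RBC up, RET% suppressed in the
  default OFF-state direction);
* the pre-analytical offset of the second event embedded in reverse, so the
  correction step recovers comparability exactly.

Covariate effects are stated on the score scale and mapped to the variable
scale through the numeric gradient of the surrogate score at the baseline
means (first-order calibration); a Monte-Carlo contract test keeps the
realized score-mean shift within tolerance of the configured ``delta_abps``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError, DataError, DomainError
from .hematology import (
    MOSCOW_CORRECTION,
    SurrogateScoreSpec,
    derive_indices,
    primary_score_gradient,
)
from .records import (
    ALTITUDE_CLASSES,
    CONTINENTS,
    ETHNICITIES,
    PRIMARY_VARIABLES,
    AthleteRecord,
    cohort_to_frame,
    frame_to_cohort,
    read_cohort_csv,
    write_cohort_csv,
)

__all__ = [
    "CohortConfig",
    "DopingEffect",
    "ScoreBaseline",
    "generate_cohort",
    "assign_ethnicity",
    "assign_altitude",
    "apply_doping_effect",
    "ETHNICITY_BY_CONTINENT",
    "ALTITUDE_PROPORTIONS",
    "GENERATOR_FACTOR_EFFECTS",
    "cohort_to_frame",
    "frame_to_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: Imposed ethnicity proportions per continent, ordered
#: (Caucasian, Asian, African, Oceanian).
ETHNICITY_BY_CONTINENT: Mapping[str, tuple[float, float, float, float]] = {
    "Europe": (1.0, 0.0, 0.0, 0.0),
    "Asia": (0.0, 1.0, 0.0, 0.0),
    "Africa": (0.0, 0.0, 1.0, 0.0),
    "NCCAmerica": (0.48, 0.07, 0.45, 0.0),
    "SouthAmerica": (0.25, 0.25, 0.25, 0.25),
    "Oceania": (0.0, 0.0, 0.0, 1.0),
}

#: Altitude allocation over (<1000, 1000-1500, 1500-2000, >2000 m) per
#: (event, endurance). Values as printed; normalized at draw time (the
#: Moscow non-endurance vector sums to 0.9999 as printed).
ALTITUDE_PROPORTIONS: Mapping[tuple[str, bool], tuple[float, ...]] = {
    ("Daegu2011", True): (0.5, 0.2, 0.2, 0.1),
    ("Daegu2011", False): (0.96, 0.02, 0.01, 0.01),
    ("Moscow2013", True): (0.5329, 0.1557, 0.1557, 0.1557),
    ("Moscow2013", False): (0.96, 0.0133, 0.0133, 0.0133),
}

#: Score-scale covariate effects materialized by the generator (the adjustment
#: model's coefficients, age handled via numeric age: <20 and >30). The event
#: offset is NOT here: it is embedded at variable scale as the inverse of the
#: pre-analytical correction.
GENERATOR_FACTOR_EFFECTS: Mapping[str, float] = {
    "Female": -0.71,
    "AgeLt20": -0.01,
    "AgeGt30": 0.05,
    "Afternoon": -0.18,
    "Evening": -0.28,
    "Africa": -0.12,
    "Asia": -0.04,
    "NCCAmerica": -0.17,
    "Oceania": -0.08,
    "SouthAmerica": -0.04,
}

_COUNTRY_SUFFIXES = "ABCDEFGH"


def _table2_defaults():
    # Compositions of the two events; the Moscow continent column prints as
    # summing to 0.99 and is renormalized so proportion invariants hold.
    moscow_continent = {
        "Africa": 0.14, "Asia": 0.12, "Europe": 0.44,
        "NCCAmerica": 0.20, "Oceania": 0.04, "SouthAmerica": 0.05,
    }
    s = sum(moscow_continent.values())
    moscow_continent = {k: v / s for k, v in moscow_continent.items()}
    return {
        "sex_prop": {
            "Daegu2011": {"M": 0.53, "F": 0.47},
            "Moscow2013": {"M": 0.56, "F": 0.44},
        },
        "age_prop": {
            "Daegu2011": {"le19": 0.02, "a19_24": 0.38, "ge25": 0.60},
            "Moscow2013": {"le19": 0.02, "a19_24": 0.40, "ge25": 0.58},
        },
        "continent_prop": {
            "Daegu2011": {
                "Africa": 0.15, "Asia": 0.16, "Europe": 0.42,
                "NCCAmerica": 0.19, "Oceania": 0.04, "SouthAmerica": 0.04,
            },
            "Moscow2013": moscow_continent,
        },
        "endurance_prop": {
            "Daegu2011": {"endurance": 0.31, "non_endurance": 0.69},
            "Moscow2013": {"endurance": 0.35, "non_endurance": 0.65},
        },
    }


@dataclass(frozen=True)
class DopingEffect:
    """Score-scale doping effect: mean shift and spread inflation.

    ``ret_direction`` selects the reticulocyte response: -1 for the OFF-state
    (suppressed RET% after a stimulation phase, the default), +1 for the
    ON-state (elevated RET% during stimulation).
    """

    delta_abps: float = 1.5
    kappa: float = 1.2
    ret_direction: int = -1


@dataclass(frozen=True)
class ScoreBaseline:
    """Score-scale baseline of the reference condition."""

    mu0: float = 0.0
    sigma0: float = 1.0


@dataclass
class CohortConfig:
    """Study conditions for one generated cohort.

    Proportion mappings may be flat (level -> fraction, applied to both
    events) or per-event (event -> level -> fraction); defaults are the two
    events' published compositions. ``prevalence`` maps stratum keys to doped
    fractions; keys are matched most-specific first among
    ``"{event}:{endurance|non_endurance}:{sex}"``, ``"{event}:{...}"``,
    ``"{event}"`` and ``"all"`` (unmatched records are clean).
    """

    n_daegu: int = 1808
    n_moscow: int = 1875
    prevalence: dict = field(
        default_factory=lambda: {
            "Daegu2011:endurance": 0.18,
            "Moscow2013:endurance": 0.15,
        }
    )
    sex_prop: dict = field(default_factory=lambda: _table2_defaults()["sex_prop"])
    age_prop: dict = field(default_factory=lambda: _table2_defaults()["age_prop"])
    continent_prop: dict = field(default_factory=lambda: _table2_defaults()["continent_prop"])
    endurance_prop: dict = field(default_factory=lambda: _table2_defaults()["endurance_prop"])
    sampling_time_prop: dict = field(
        default_factory=lambda: {"morning": 0.5, "afternoon": 0.3, "evening": 0.2}
    )
    doping_effect: DopingEffect = field(default_factory=DopingEffect)
    baseline: ScoreBaseline = field(default_factory=ScoreBaseline)
    hematology_baseline: dict = field(
        default_factory=lambda: {
            "HGB": (15.2, 0.9), "HCT": (45.0, 2.5), "RBC": (5.0, 0.3), "RET_pct": (1.2, 0.25),
        }
    )
    score_spec: SurrogateScoreSpec = field(default_factory=SurrogateScoreSpec)
    factor_effects: dict = field(default_factory=lambda: dict(GENERATOR_FACTOR_EFFECTS))
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def _per_event(self, mapping: Mapping, name: str) -> dict:
        """Return {event: {level: fraction}} from a flat or per-event mapping."""
        if all(isinstance(v, Mapping) for v in mapping.values()):
            return {e: dict(v) for e, v in mapping.items()}
        return {"Daegu2011": dict(mapping), "Moscow2013": dict(mapping)}

    def validate(self) -> None:
        named = {
            "sex_prop": self.sex_prop,
            "age_prop": self.age_prop,
            "continent_prop": self.continent_prop,
            "endurance_prop": self.endurance_prop,
            "sampling_time_prop": self.sampling_time_prop,
        }
        for name, mapping in named.items():
            per_event = self._per_event(mapping, name)
            for event, levels in per_event.items():
                total = sum(levels.values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"{name}[{event}] sums to {total!r}, expected 1 within 1e-9"
                    )
                if any(v < 0 for v in levels.values()):
                    raise ConfigError(f"{name}[{event}] contains negative proportions")
        for key, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"prevalence[{key!r}]={p} outside [0, 1]")
        if not self.baseline.sigma0 > 0:
            raise ConfigError("baseline sigma0 must be > 0")
        if self.doping_effect.kappa < 1.0:
            raise ConfigError("doping spread multiplier kappa must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        """Load a config from a nested key-value file; all defaults overridable."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, value in raw.items():
            if key == "doping_effect":
                kwargs[key] = DopingEffect(**value)
            elif key == "baseline":
                kwargs[key] = ScoreBaseline(**value)
            elif key == "hematology_baseline":
                kwargs[key] = {k: tuple(v) for k, v in value.items()}
            else:
                kwargs[key] = value
        return cls(**kwargs)


def resolve_prevalence(prevalence: Mapping[str, float], event: str,
                       endurance: bool, sex: str) -> float:
    """Most-specific-first lookup of the doped fraction for a record's stratum."""
    sport = "endurance" if endurance else "non_endurance"
    for key in (f"{event}:{sport}:{sex}", f"{event}:{sport}", event, "all"):
        if key in prevalence:
            return prevalence[key]
    return 0.0


def assign_ethnicity(continent: str, rng: np.random.Generator) -> str:
    """Draw an ethnicity from the continent's imposed proportion vector."""
    if continent not in ETHNICITY_BY_CONTINENT:
        raise DomainError(f"unknown continent {continent!r}")
    probs = ETHNICITY_BY_CONTINENT[continent]
    return str(rng.choice(ETHNICITIES, p=probs))


def assign_altitude(endurance: bool, event: str, rng: np.random.Generator) -> str:
    """Draw a prior-altitude class from the event- and discipline-specific allocation."""
    probs = np.asarray(ALTITUDE_PROPORTIONS[(event, bool(endurance))], dtype=float)
    return str(rng.choice(ALTITUDE_CLASSES, p=probs / probs.sum()))


def _effect_calibration(config: CohortConfig):
    """Variable-scale directions producing unit score-scale shifts.

    Returns (covariate_shift_per_unit_score, doped_shift_vector) over the
    four primary variables.
    """
    means = {v: config.hematology_baseline[v][0] for v in PRIMARY_VARIABLES}
    sds = np.array([config.hematology_baseline[v][1] for v in PRIMARY_VARIABLES])
    grad = primary_score_gradient(config.score_spec, means)
    u_cov = sds * np.array([1.0, 1.0, 1.0, 0.0])
    u_dope = sds * np.array([1.0, 1.0, 1.0, float(config.doping_effect.ret_direction)])
    cov_unit = u_cov / float(grad @ u_cov)
    dope_shift = u_dope * (config.doping_effect.delta_abps / float(grad @ u_dope))
    return cov_unit, dope_shift


def _covariate_score_effects(config, sex, age, time, continent):
    eff = np.zeros(len(sex))
    fe = config.factor_effects
    eff += np.where(sex == "F", fe.get("Female", 0.0), 0.0)
    eff += np.where(age < 20, fe.get("AgeLt20", 0.0), 0.0)
    eff += np.where(age > 30, fe.get("AgeGt30", 0.0), 0.0)
    eff += np.where(time == "afternoon", fe.get("Afternoon", 0.0), 0.0)
    eff += np.where(time == "evening", fe.get("Evening", 0.0), 0.0)
    for cont in CONTINENTS:
        if cont == "Europe":
            continue
        eff += np.where(continent == cont, fe.get(cont, 0.0), 0.0)
    return eff


def _draw_ages(rng, age_class):
    """Numeric age consistent with the class (exact-19 ties go to the first class)."""
    n = len(age_class)
    age = np.empty(n)
    lo = {"le19": 16.0, "a19_24": 19.0, "ge25": 25.0}
    hi = {"le19": 19.0, "a19_24": 25.0, "ge25": 38.0}
    u = rng.random(n)
    for cls in ("le19", "a19_24", "ge25"):
        m = age_class == cls
        age[m] = lo[cls] + u[m] * (hi[cls] - lo[cls])
    return age


def generate_cohort(config: CohortConfig | None = None) -> list[AthleteRecord]:
    """Generate one cohort of athlete records under the configured conditions.

    Returns exactly ``n_daegu + n_moscow`` records, fully reproducible given
    ``config.seed``. Hematological variables are drawn from the clean baseline
    shifted by covariate effects and, for doped records, the calibrated doping
    effect (with spread inflated by kappa); raw values of the second event
    additionally carry the inverse of the pre-analytical correction so the
    correction step recovers comparability. Gaussian noise that would drive a
    variable nonpositive is redrawn (negligible truncation at the default
    baselines).
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    cov_unit, dope_shift = _effect_calibration(config)
    means = np.array([config.hematology_baseline[v][0] for v in PRIMARY_VARIABLES])
    sds = np.array([config.hematology_baseline[v][1] for v in PRIMARY_VARIABLES])
    moscow_bias = np.array([MOSCOW_CORRECTION[v] for v in PRIMARY_VARIABLES])

    records: list[AthleteRecord] = []
    for event, n in (("Daegu2011", config.n_daegu), ("Moscow2013", config.n_moscow)):
        if n == 0:
            continue
        sex_p = config._per_event(config.sex_prop, "sex_prop")[event]
        age_p = config._per_event(config.age_prop, "age_prop")[event]
        cont_p = config._per_event(config.continent_prop, "continent_prop")[event]
        end_p = config._per_event(config.endurance_prop, "endurance_prop")[event]
        time_p = config._per_event(config.sampling_time_prop, "sampling_time_prop")[event]

        sex = rng.choice(list(sex_p), size=n, p=list(sex_p.values()))
        age_class = rng.choice(list(age_p), size=n, p=list(age_p.values()))
        age = _draw_ages(rng, age_class)
        continent = rng.choice(list(cont_p), size=n, p=list(cont_p.values()))
        ethnicity = np.empty(n, dtype=object)
        for cont in CONTINENTS:
            m = continent == cont
            if m.any():
                ethnicity[m] = rng.choice(
                    ETHNICITIES, size=int(m.sum()), p=ETHNICITY_BY_CONTINENT[cont]
                )
        country = np.array(
            [f"{c[:2].upper()}-{s}" for c, s in
             zip(continent, rng.choice(list(_COUNTRY_SUFFIXES), size=n))],
            dtype=object,
        )
        endurance = rng.random(n) < end_p["endurance"]
        altitude = np.empty(n, dtype=object)
        for flag in (True, False):
            m = endurance == flag
            if m.any():
                probs = np.asarray(ALTITUDE_PROPORTIONS[(event, flag)], dtype=float)
                altitude[m] = rng.choice(
                    ALTITUDE_CLASSES, size=int(m.sum()), p=probs / probs.sum()
                )
        time = rng.choice(list(time_p), size=n, p=list(time_p.values()))

        pi = np.array(
            [resolve_prevalence(config.prevalence, event, e, s)
             for e, s in zip(endurance, sex)]
        )
        doped = rng.random(n) < pi

        eff = _covariate_score_effects(config, sex, age, time, continent)
        cond_mean = means + eff[:, None] * cov_unit[None, :]
        shift = np.where(doped[:, None], dope_shift[None, :], 0.0)
        noise_sd = np.where(doped[:, None], config.doping_effect.kappa, 1.0) * sds[None, :]
        event_bias = -moscow_bias if event == "Moscow2013" else np.zeros(4)
        target_mean = cond_mean + shift + event_bias[None, :]
        values = target_mean + noise_sd * rng.standard_normal((n, 4))
        # redraw noise wherever a variable would come out nonpositive
        for _ in range(100):
            bad = values <= 0.0
            if not bad.any():
                break
            values[bad] = (target_mean + noise_sd * rng.standard_normal((n, 4)))[bad]
        else:  # pragma: no cover - defensive
            raise DataError("could not draw strictly positive hematological values")

        mcv, mch, mchc = derive_indices(values[:, 0], values[:, 1], values[:, 2])
        for i in range(n):
            records.append(
                AthleteRecord(
                    athlete_id=f"{event}-{i:05d}",
                    event=event,
                    sex=str(sex[i]),
                    age_class=str(age_class[i]),
                    age=float(age[i]),
                    country=str(country[i]),
                    continent=str(continent[i]),
                    ethnicity=str(ethnicity[i]),
                    endurance=bool(endurance[i]),
                    altitude_class=str(altitude[i]),
                    sampling_time=str(time[i]),
                    HGB=float(values[i, 0]),
                    HCT=float(values[i, 1]),
                    RBC=float(values[i, 2]),
                    RET_pct=float(values[i, 3]),
                    MCV=float(mcv[i]),
                    MCH=float(mch[i]),
                    MCHC=float(mchc[i]),
                    doped=bool(doped[i]),
                )
            )
    return records


def apply_doping_effect(
    record: AthleteRecord,
    effect: DopingEffect | None = None,
    rng: np.random.Generator | None = None,
    config: CohortConfig | None = None,
) -> AthleteRecord:
    """Perturb a doped record's variables in the rhEPO-microdose direction.

    The four primary variables move along the calibrated doping direction
    (HGB/HCT/RBC up; RET% along ``ret_direction``) so that the surrogate
    score's population mean increases by ``delta_abps``; deviations from the
    clean conditional mean are inflated by ``kappa``. The derived indices are
    recomputed from the perturbed primaries. The transform is deterministic
    given the record; ``rng`` is accepted for signature stability.

    Calling this on a clean record is a contract violation.
    """
    if record.doped is not True:
        raise DomainError("apply_doping_effect requires a record with doped=True")
    config = config or CohortConfig()
    effect = effect or config.doping_effect
    if effect is not config.doping_effect:
        config = dataclasses.replace(config, doping_effect=effect)
    cov_unit, dope_shift = _effect_calibration(config)
    means = np.array([config.hematology_baseline[v][0] for v in PRIMARY_VARIABLES])
    age = record.age if record.age is not None else {"le19": 18.0, "a19_24": 22.0, "ge25": 28.0}[record.age_class]
    eff = _covariate_score_effects(
        config,
        np.array([record.sex]), np.array([age]),
        np.array([record.sampling_time]), np.array([record.continent]),
    )[0]
    cond_mean = means + eff * cov_unit
    x = np.array([getattr(record, v) for v in PRIMARY_VARIABLES])
    new = cond_mean + effect.kappa * (x - cond_mean) + dope_shift
    if np.any(new <= 0):
        raise DataError("doping effect drives a hematological variable nonpositive")
    mcv, mch, mchc = derive_indices(new[0], new[1], new[2])
    return record.replace(
        HGB=float(new[0]), HCT=float(new[1]), RBC=float(new[2]), RET_pct=float(new[3]),
        MCV=float(mcv), MCH=float(mch), MCHC=float(mchc),
    )
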