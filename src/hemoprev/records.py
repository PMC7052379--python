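"""Per-athlete blood-test records and their CSV dialect.

One :class:`AthleteRecord` is one blood test: the covariates used by the
reference model (event, sex, age class, origin, endurance flag, altitude
class, sampling time) plus the seven hematological variables the
multiparametric score is computed from. The three red-cell indices are not
independent measurements: they are tied to the primary variables by the
identities MCV = 10*HCT/RBC, MCH = 10*HGB/RBC and MCHC = 100*HGB/HCT, and
every operation that touches a primary variable re-derives them.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

EVENTS = ("Daegu2011", "Moscow2013")
SEXES = ("M", "F")
AGE_CLASSES = ("le19", "a19_24", "ge25")
CONTINENTS = ("Africa", "Asia", "Europe", "NCCAmerica", "Oceania", "SouthAmerica")
ETHNICITIES = ("Caucasian", "Asian", "African", "Oceanian")
ALTITUDE_CLASSES = ("lt1000", "a1000_1500", "a1500_2000", "gt2000")
SAMPLING_TIMES = ("morning", "afternoon", "evening")

#: Primary hematological variables (measured; corrected for pre-analytical bias).
PRIMARY_VARIABLES = ("HGB", "HCT", "RBC", "RET_pct")
#: Red-cell indices derived from the primaries.
DERIVED_VARIABLES = ("MCV", "MCH", "MCHC")
ALL_VARIABLES = PRIMARY_VARIABLES + DERIVED_VARIABLES

_FIELD_ORDER = (
    "athlete_id",
    "event",
    "sex",
    "age_class",
    "age",
    "country",
    "continent",
    "ethnicity",
    "endurance",
    "altitude_class",
    "sampling_time",
    "HGB",
    "HCT",
    "RBC",
    "RET_pct",
    "MCV",
    "MCH",
    "MCHC",
    "abps",
    "doped",
)


@dataclass
class AthleteRecord:
    """A single blood test with covariates and hematological variables.

    Units: HGB g/dL, HCT %, RBC 10^6/uL, RET_pct %, MCV fL, MCH pg, MCHC g/dL.
    ``abps`` (score units) and ``doped`` (synthetic ground truth) are optional.
    ``age`` (years) is optional and supports the alternative <20 / >30 age
    stratification used by the adjustment model.
    """

    athlete_id: str
    event: str
    sex: str
    age_class: str
    country: str
    continent: str
    ethnicity: str
    endurance: bool
    altitude_class: str
    sampling_time: str
    HGB: float
    HCT: float
    RBC: float
    RET_pct: float
    MCV: float
    MCH: float
    MCHC: float
    age: float | None = None
    abps: float | None = None
    doped: bool | None = None

    def validate(self, rtol: float = 1e-6) -> None:
        """Check positivity of the seven variables and the index identities."""
        for name in ALL_VARIABLES:
            value = getattr(self, name)
            if not value > 0:
                raise DataError(f"{name} must be strictly positive, got {value!r}")
        expected = (
            10.0 * self.HCT / self.RBC,
            10.0 * self.HGB / self.RBC,
            100.0 * self.HGB / self.HCT,
        )
        for name, exp in zip(DERIVED_VARIABLES, expected):
            got = getattr(self, name)
            if not math.isclose(got, exp, rel_tol=rtol):
                raise DataError(
                    f"derived index {name}={got} inconsistent with primaries (expected {exp})"
                )

    def replace(self, **changes) -> "AthleteRecord":
        return dataclasses.replace(self, **changes)


def cohort_to_frame(records: Iterable[AthleteRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame with one column per field."""
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows)
    return df.reindex(columns=list(_FIELD_ORDER))


def frame_to_cohort(df: pd.DataFrame) -> list[AthleteRecord]:
    """Convert a cohort DataFrame back into records."""
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for opt in ("age", "abps", "doped"):
            if opt in d and (d[opt] is None or (isinstance(d[opt], float) and np.isnan(d[opt]))):
                d[opt] = None
        if d.get("doped") is not None:
            d["doped"] = bool(d["doped"])
        d["endurance"] = bool(d["endurance"])
        records.append(AthleteRecord(**{k: d[k] for k in _FIELD_ORDER if k in d}))
    return records


def write_cohort_csv(cohort: Sequence[AthleteRecord] | pd.DataFrame, path) -> None:
    """Write a cohort as CSV (one header row; missing optional fields empty)."""
    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    df.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    df = pd.read_csv(path)
    if "endurance" in df.columns and df["endurance"].dtype != bool:
        df["endurance"] = df["endurance"].astype(str).str.lower().isin(("true", "1"))
    if "doped" in df.columns and df["doped"].dtype == object:
        df["doped"] = df["doped"].map(
            lambda v: None if pd.isna(v) else str(v).lower() in ("true", "1")
        )
    return df
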