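"""Red-cell index formulas, pre-analytical corrections, and the blood profile score.

The two events were analyzed on different instruments and a systematic,
non-biological offset exists between them. Because the seven hematological
variables are interdependent, only the four primary variables (HGB, HCT, RBC,
RET%) carry an additive correction; the three derived indices are always
recomputed from the corrected primaries:

    MCV = 10 * HCT / RBC,  MCH = 10 * HGB / RBC,  MCHC = 100 * HGB / HCT.

The Abnormal Blood Profile Score (ABPS) is a multiparametric abnormality
measure over the seven variables; the original classifier is proprietary, so
this module provides a transparent linear surrogate over standardized
variables with the same interface (higher under erythropoietic blood doping:
HGB/HCT/RBC push the score up, RET% pulls it down under default weights).
Real ABPS values supplied in an input CSV bypass the surrogate entirely —
all downstream logic is score-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, DomainError
from .records import (
    ALL_VARIABLES,
    DERIVED_VARIABLES,
    PRIMARY_VARIABLES,
    AthleteRecord,
)

#: Additive pre-analytical correction factors (applied to raw values of the
#: second event to map them onto the first event's scale).
MOSCOW_CORRECTION = MappingProxyType(
    {"HGB": -0.3, "HCT": -0.7, "RBC": -0.08, "RET_pct": +0.07}
)
_ZERO_CORRECTION = MappingProxyType({v: 0.0 for v in PRIMARY_VARIABLES})


def derive_indices(HGB, HCT, RBC):
    """Derive (MCV, MCH, MCHC) from the primary variables.

    Accepts scalars or arrays; all inputs must be strictly positive.
    """
    for name, value in (("HGB", HGB), ("HCT", HCT), ("RBC", RBC)):
        if np.any(np.asarray(value) <= 0):
            raise DomainError(f"{name} must be strictly positive")
    return 10.0 * HCT / RBC, 10.0 * HGB / RBC, 100.0 * HGB / HCT


@dataclass(frozen=True)
class CorrectionFactors:
    """Per-event additive shifts for the four primary variables."""

    shifts: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "Daegu2011": dict(_ZERO_CORRECTION),
            "Moscow2013": dict(MOSCOW_CORRECTION),
        }
    )

    def for_event(self, event: str) -> Mapping[str, float]:
        return self.shifts.get(event, _ZERO_CORRECTION)


def correct_preanalytical(
    record: AthleteRecord, factors: CorrectionFactors | None = None
) -> AthleteRecord:
    """Apply the event's additive correction and re-derive the indices.

    Records from the reference event (zero factors) pass through unchanged
    field-for-field. A corrected value <= 0 is a data error; values are never
    silently clipped.
    """
    factors = factors or CorrectionFactors()
    shift = factors.for_event(record.event)
    corrected = {v: getattr(record, v) + shift.get(v, 0.0) for v in PRIMARY_VARIABLES}
    bad = [v for v, x in corrected.items() if x <= 0]
    if bad:
        raise DataError(
            f"correction drives {', '.join(bad)} nonpositive for athlete {record.athlete_id}"
        )
    mcv, mch, mchc = derive_indices(corrected["HGB"], corrected["HCT"], corrected["RBC"])
    return record.replace(**corrected, MCV=mcv, MCH=mch, MCHC=mchc)


def correct_cohort(df: pd.DataFrame, factors: CorrectionFactors | None = None) -> pd.DataFrame:
    """Vectorized :func:`correct_preanalytical` over a cohort DataFrame."""
    factors = factors or CorrectionFactors()
    out = df.copy()
    for event in out["event"].unique():
        shift = factors.for_event(event)
        mask = out["event"] == event
        for v in PRIMARY_VARIABLES:
            out.loc[mask, v] = out.loc[mask, v] + shift.get(v, 0.0)
    bad = out[list(PRIMARY_VARIABLES)].le(0).any(axis=1)
    if bad.any():
        ids = out.loc[bad, "athlete_id"].tolist()[:5]
        raise DataError(f"correction drives primary variables nonpositive for {ids} ...")
    out["MCV"], out["MCH"], out["MCHC"] = derive_indices(out["HGB"], out["HCT"], out["RBC"])
    return out


def _default_means() -> dict[str, float]:
    # Clean morning European male reference (first event); derived entries
    # follow the index identities exactly.
    hgb, hct, rbc, ret = 15.2, 45.0, 5.0, 1.2
    mcv, mch, mchc = 10.0 * hct / rbc, 10.0 * hgb / rbc, 100.0 * hgb / hct
    return {
        "HGB": hgb, "HCT": hct, "RBC": rbc, "RET_pct": ret,
        "MCV": mcv, "MCH": mch, "MCHC": mchc,
    }


@dataclass(frozen=True)
class SurrogateScoreSpec:
    """Linear surrogate score over standardized hematological variables.

    score = normalization * sum_j weight_j * (x_j - mean_j) / spread_j
    """

    means: Mapping[str, float] = field(default_factory=_default_means)
    spreads: Mapping[str, float] = field(
        default_factory=lambda: {
            "HGB": 0.9, "HCT": 2.5, "RBC": 0.3, "RET_pct": 0.25,
            "MCV": 4.0, "MCH": 1.5, "MCHC": 1.0,
        }
    )
    weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "HGB": 1.0, "HCT": 1.0, "RBC": 1.0, "RET_pct": -1.0,
            "MCV": 0.25, "MCH": 0.25, "MCHC": 0.25,
        }
    )
    normalization: float = 1.0 / math.sqrt(7.0)

    def __post_init__(self):
        for v in ALL_VARIABLES:
            if not np.isfinite(self.weights[v]):
                raise DomainError(f"weight for {v} must be finite")
            if not self.spreads[v] > 0:
                raise DomainError(f"spread for {v} must be strictly positive")


def compute_abps(record: AthleteRecord | Mapping[str, float],
                 spec: SurrogateScoreSpec | None = None) -> float:
    """Compute the surrogate score for one record.

    Deterministic; strictly monotone increasing in HGB and decreasing in RET%
    under default weights. Missing variables are a data error.
    """
    spec = spec or SurrogateScoreSpec()
    get = record.get if isinstance(record, Mapping) else lambda v, d=None: getattr(record, v, d)
    missing = [v for v in ALL_VARIABLES if get(v) is None]
    if missing:
        raise DataError(f"missing hematological variables: {', '.join(missing)}")
    total = 0.0
    for v in ALL_VARIABLES:
        x = get(v)
        if x <= 0:
            raise DataError(f"{v} must be strictly positive, got {x!r}")
        total += spec.weights[v] * (x - spec.means[v]) / spec.spreads[v]
    return spec.normalization * total


def score_cohort(df: pd.DataFrame, spec: SurrogateScoreSpec | None = None) -> np.ndarray:
    """Vectorized surrogate score over a cohort DataFrame."""
    spec = spec or SurrogateScoreSpec()
    missing = [v for v in ALL_VARIABLES if v not in df.columns]
    if missing:
        raise DataError(f"missing hematological variables: {', '.join(missing)}")
    total = np.zeros(len(df))
    for v in ALL_VARIABLES:
        x = df[v].to_numpy(dtype=float)
        if np.any(x <= 0):
            raise DataError(f"{v} must be strictly positive")
        total += spec.weights[v] * (x - spec.means[v]) / spec.spreads[v]
    return spec.normalization * total


def primary_score_gradient(
    spec: SurrogateScoreSpec | None = None,
    at: Mapping[str, float] | None = None,
    eps: float = 1e-5,
) -> np.ndarray:
    """Numeric gradient of the score w.r.t. the four primary variables.

    The derived indices are recomputed inside the difference quotient, so the
    gradient accounts for the full primaries -> indices -> score chain. Used
    to calibrate effect directions on the variable scale against targets
    stated on the score scale.
    """
    spec = spec or SurrogateScoreSpec()
    at = dict(at) if at is not None else {v: spec.means[v] for v in PRIMARY_VARIABLES}

    def score_of(primaries: Mapping[str, float]) -> float:
        mcv, mch, mchc = derive_indices(primaries["HGB"], primaries["HCT"], primaries["RBC"])
        values = dict(primaries, MCV=mcv, MCH=mch, MCHC=mchc)
        return compute_abps(values, spec)

    grad = np.empty(len(PRIMARY_VARIABLES))
    for i, v in enumerate(PRIMARY_VARIABLES):
        hi, lo = dict(at), dict(at)
        hi[v] += eps
        lo[v] -= eps
        grad[i] = (score_of(hi) - score_of(lo)) / (2.0 * eps)
    return grad
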