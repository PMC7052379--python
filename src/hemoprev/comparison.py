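"""Between-event distribution comparisons with FDR control.

Adjusted score samples from the two events are compared per stratum with two
rank-based two-sample tests: Kolmogorov-Smirnov (largest vertical distance
between the empirical CDFs) and Cramér-von Mises (integrated squared
distance over the pooled order statistics). Raw p-values are adjusted per
test family across strata with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DomainError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonResult:
    """Both tests' statistics and (adjusted) p-values for one stratum."""

    stratum: str
    n_a: int
    n_b: int
    ks_stat: float
    ks_p: float
    cvm_stat: float
    cvm_p: float
    ks_p_adj: float = float("nan")
    cvm_p_adj: float = float("nan")


@dataclass(frozen=True)
class StrataSpec:
    """Which strata to compare and the minimum sizes for inclusion.

    A stratum is compared when both events have at least ``min_n`` samples
    (``min_n_female`` for female-only strata); smaller strata are excluded
    with a logged notice.
    """

    by_sex: bool = True
    by_country: bool = True
    min_n: int = 10
    min_n_female: int = 7


def _check_samples(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be non-empty")
    return x, y


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Statistic: the supremum over pooled points of |F_x - F_y|; p-value from
    the asymptotic distribution at effective size n_x*n_y/(n_x+n_y).
    """
    x, y = _check_samples(x, y)
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def cvm_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Cramér-von Mises test.

    Statistic: (n_x*n_y/(n_x+n_y)^2) * sum over pooled order statistics of
    (F_x - F_y)^2; p-value from the standard asymptotic distribution.
    """
    x, y = _check_samples(x, y)
    res = stats.cramervonmises_2samp(x, y, method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in original order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity by cumulative
    minimum from the largest, cap at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_strata(
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    spec: StrataSpec | None = None,
    score_col: str = "abps_adjusted",
) -> list[ComparisonResult]:
    """Apply both tests per stratum and BH-adjust each family across strata.

    Strata are "All", per sex, and per country (levels pooled over the two
    cohorts). The KS and CvM families are adjusted separately, mirroring the
    two adjusted-p columns of the published tables.
    """
    spec = spec or StrataSpec()
    pooled_countries = sorted(
        set(cohort_a.get("country", pd.Series(dtype=object)).dropna())
        | set(cohort_b.get("country", pd.Series(dtype=object)).dropna())
    )
    partial: list[ComparisonResult] = []
    strata: list[tuple[str, bool]] = [("All", False)]
    if spec.by_sex:
        strata += [("Female", True), ("Male", False)]
    if spec.by_country:
        strata += [(c, False) for c in pooled_countries]
    for label, is_female in strata:
        if label == "All":
            xa, xb = cohort_a, cohort_b
        elif label in ("Female", "Male"):
            s = "F" if label == "Female" else "M"
            xa, xb = cohort_a[cohort_a["sex"] == s], cohort_b[cohort_b["sex"] == s]
        else:
            xa = cohort_a[cohort_a["country"] == label]
            xb = cohort_b[cohort_b["country"] == label]
        x = xa[score_col].to_numpy(dtype=float)
        y = xb[score_col].to_numpy(dtype=float)
        threshold = spec.min_n_female if is_female else spec.min_n
        if min(x.size, y.size) < threshold:
            logger.info(
                "stratum %s excluded: n=(%d, %d) below minimum %d",
                label, x.size, y.size, threshold,
            )
            continue
        ks_stat, ks_p = ks_two_sample(x, y)
        cvm_stat, cvm_p = cvm_two_sample(x, y)
        partial.append(
            ComparisonResult(
                stratum=label, n_a=x.size, n_b=y.size,
                ks_stat=ks_stat, ks_p=ks_p, cvm_stat=cvm_stat, cvm_p=cvm_p,
            )
        )
    if not partial:
        return []
    ks_adj = benjamini_hochberg([r.ks_p for r in partial])
    cvm_adj = benjamini_hochberg([r.cvm_p for r in partial])
    return [
        ComparisonResult(
            stratum=r.stratum, n_a=r.n_a, n_b=r.n_b,
            ks_stat=r.ks_stat, ks_p=r.ks_p,
            cvm_stat=r.cvm_stat, cvm_p=r.cvm_p,
            ks_p_adj=float(ka), cvm_p_adj=float(ca),
        )
        for r, ka, ca in zip(partial, ks_adj, cvm_adj)
    ]


def results_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tabulate comparison results (one row per stratum)."""
    return pd.DataFrame([r.__dict__ for r in results])
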