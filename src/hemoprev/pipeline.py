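"""End-to-end orchestration: I/O, deduplication, stratification, reporting.

The pipeline chains the package's stages on a cohort (loaded from CSV or
simulated): deduplicate -> pre-analytical correction -> score -> covariate
adjustment -> per-stratum reference CDFs -> prevalence with bootstrap CIs ->
between-event comparisons -> tables. Every random stage is seeded from the
config and every decision (mode switches, excluded strata, floored
estimates) is logged, so runs are reproducible byte for byte.

The event offset can be removed in exactly one of two ways (the config makes
this structural): ``"variable"`` applies the additive pre-analytical
correction to HGB/HCT/RBC/RET% before scoring (the adjustment model's event
coefficient is then disabled), while ``"score"`` leaves the variables alone
and subtracts the score-scale event coefficient during adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adjustment, comparison, hematology, prevalence, synthetic_cohort
from .errors import ConfigError, DataError, DomainError
from .records import cohort_to_frame, read_cohort_csv

logger = logging.getLogger(__name__)

#: Championship discipline table: label -> (kind, distance in meters or None).
DISCIPLINES = {
    "100m": ("run", 100), "200m": ("run", 200), "400m": ("run", 400),
    "800m": ("run", 800), "1500m": ("run", 1500), "3000m_steeplechase": ("run", 3000),
    "5000m": ("run", 5000), "10000m": ("run", 10000), "marathon": ("run", 42195),
    "110m_hurdles": ("run", 110), "100m_hurdles": ("run", 100),
    "400m_hurdles": ("run", 400),
    "4x100m_relay": ("relay", 400), "4x400m_relay": ("relay", 1600),
    "20km_race_walk": ("walk", 20000), "50km_race_walk": ("walk", 50000),
    "high_jump": ("jump", None), "pole_vault": ("jump", None),
    "long_jump": ("jump", None), "triple_jump": ("jump", None),
    "shot_put": ("throw", None), "discus_throw": ("throw", None),
    "hammer_throw": ("throw", None), "javelin_throw": ("throw", None),
    "decathlon": ("combined", None), "heptathlon": ("combined", None),
}


def classify_endurance(discipline: str) -> bool:
    """True iff the discipline is a running or walking event of >= 800 m.

    Jumps, sprints, hurdles, throws, combined events and relays are
    non-endurance. Unknown disciplines are a domain error.
    """
    if discipline not in DISCIPLINES:
        raise DomainError(f"unknown discipline {discipline!r}")
    kind, distance = DISCIPLINES[discipline]
    return kind in ("run", "walk") and distance is not None and distance >= 800


def deduplicate_first(df: pd.DataFrame) -> pd.DataFrame:
    """Keep the earliest record per athlete per event.

    Records are ordered by a ``timestamp`` column when present (stable sort,
    so identical timestamps keep file order), else by file order.
    """
    if "athlete_id" not in df.columns or df["athlete_id"].isna().any():
        raise DataError("records must carry an athlete_id")
    out = df
    if "timestamp" in df.columns:
        out = df.sort_values("timestamp", kind="stable")
    out = out.drop_duplicates(subset=["athlete_id", "event"], keep="first")
    return out.loc[df.index.intersection(out.index)]


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    input_csv: str | None = None
    simulate: bool = True
    cohort: synthetic_cohort.CohortConfig = field(
        default_factory=synthetic_cohort.CohortConfig
    )
    moscow_correction: str = "variable"  # "variable" | "score"
    adjustment_mode: str = "default"  # "default" | "refit"
    reference: prevalence.ReferenceModel = field(default_factory=prevalence.ReferenceModel)
    reference_n: int = 100_000
    grid: prevalence.GridSpec = field(default_factory=prevalence.GridSpec)
    strata: comparison.StrataSpec = field(default_factory=comparison.StrataSpec)
    cell_min_n: int = 5  # smallest per-event stratum reported in tables
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    outdir: str = "hemoprev_out"

    def __post_init__(self):
        if self.moscow_correction not in ("variable", "score"):
            raise ConfigError(
                "moscow_correction must be exactly one of 'variable' or 'score'"
            )
        if self.adjustment_mode not in ("default", "refit"):
            raise ConfigError("adjustment_mode must be 'default' or 'refit'")
        if not self.simulate and not self.input_csv:
            raise ConfigError("either simulate=True or an input_csv is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, value in raw.items():
            if key == "cohort":
                kwargs[key] = synthetic_cohort.CohortConfig(**value)
            elif key == "reference":
                kwargs[key] = prevalence.ReferenceModel(**value)
            elif key == "grid":
                kwargs[key] = prevalence.GridSpec(**value)
            elif key == "strata":
                kwargs[key] = comparison.StrataSpec(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class PipelineReport:
    """All artifacts of one pipeline run."""

    cohort: pd.DataFrame
    prevalence_table: pd.DataFrame
    comparison_table: pd.DataFrame
    reference_curves: pd.DataFrame
    paths: dict


def _anonymize_countries(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Replace country labels with 'Country A', 'Country B', ... (sorted)."""
    mapping = {}
    labels = sorted(df["country"].dropna().unique())
    for i, label in enumerate(labels):
        letters = ""
        k = i
        while True:
            letters = chr(ord("A") + k % 26) + letters
            k = k // 26 - 1
            if k < 0:
                break
        mapping[label] = f"Country {letters}"
    out = df.copy()
    out["country"] = out["country"].map(mapping)
    return out, mapping


def _load_cohort(config: PipelineConfig) -> pd.DataFrame:
    if config.simulate:
        cohort_cfg = replace(config.cohort, seed=config.seed)
        records = synthetic_cohort.generate_cohort(cohort_cfg)
        return cohort_to_frame(records)
    return read_cohort_csv(config.input_csv)


def run_pipeline(config: PipelineConfig | None = None, write: bool = True) -> PipelineReport:
    """Execute the full analysis and (optionally) write the report CSVs."""
    config = config or PipelineConfig()
    rng_seq = np.random.SeedSequence(config.seed)
    seeds = rng_seq.generate_state(4) % (2**31)

    df = _load_cohort(config)
    df = deduplicate_first(df)

    if config.moscow_correction == "variable":
        logger.info("removing event offset at variable scale (pre-analytical correction)")
        df = hematology.correct_cohort(df)
    else:
        logger.info("removing event offset at score scale (event coefficient)")

    if "abps" not in df.columns or df["abps"].isna().any():
        df = df.copy()
        df["abps"] = hematology.score_cohort(df)

    if config.adjustment_mode == "refit":
        model = adjustment.fit_adjustment_model(df)
    else:
        model = adjustment.default_model()
    if config.moscow_correction == "variable":
        # variables already corrected for the event offset; do not correct twice
        model = model.without("Moscow")
    df = df.copy()
    df["abps_adjusted"] = adjustment.adjust_scores(df, model)

    clean = prevalence.simulate_reference_population(
        config.reference, None, False, config.reference_n, int(seeds[0])
    )
    dope = prevalence.simulate_reference_population(
        config.reference, None, True, config.reference_n, int(seeds[1])
    )
    refs = prevalence.build_reference_cdfs(clean, dope, config.grid)

    endurance = df[df["endurance"]].copy()
    endurance, country_map = _anonymize_countries(endurance)
    boot_rng = np.random.default_rng(int(seeds[2]))

    rows = []
    strata: list[tuple[str, str | None, str | None]] = [("All", None, None)]
    if config.strata.by_sex:
        strata += [("Female", "F", None), ("Male", "M", None)]
    countries = sorted(endurance["country"].dropna().unique())
    if config.strata.by_country:
        for country in countries:
            strata.append((country, None, country))
    for label, sex, country in strata:
        sub = endurance
        if sex is not None:
            sub = sub[sub["sex"] == sex]
        if country is not None:
            sub = sub[sub["country"] == country]
        n_by_event = {e: int((sub["event"] == e).sum()) for e in ("Daegu2011", "Moscow2013")}
        if country is not None and max(n_by_event.values()) < config.strata.min_n:
            logger.info("stratum %s excluded from tables: n=%s", label, n_by_event)
            continue
        row = {"stratum": label}
        for event, tag in (("Daegu2011", "2011"), ("Moscow2013", "2013")):
            scores = sub.loc[sub["event"] == event, "abps_adjusted"].to_numpy()
            row[f"n_{tag}"] = scores.size
            if scores.size < config.cell_min_n:
                logger.info("stratum %s, %s left blank: n=%d", label, event, scores.size)
                row[f"prevalence_{tag}"] = np.nan
                row[f"prevalence_raw_{tag}"] = np.nan
                row[f"ci_low_{tag}"] = np.nan
                row[f"ci_high_{tag}"] = np.nan
                continue
            est = prevalence.estimate_stratum(
                scores, refs, stratum=label,
                n_boot=config.n_boot, level=config.ci_level, seed=boot_rng,
            )
            if est.estimate < 0:
                logger.info(
                    "stratum %s, %s: raw estimate %.4f floored to 0.00 in table",
                    label, event, est.estimate,
                )
            row[f"prevalence_{tag}"] = max(est.estimate, 0.0)
            row[f"prevalence_raw_{tag}"] = est.estimate
            row[f"ci_low_{tag}"] = est.ci_low
            row[f"ci_high_{tag}"] = est.ci_high
        rows.append(row)
    prevalence_table = pd.DataFrame(rows)

    results = comparison.compare_strata(
        endurance[endurance["event"] == "Daegu2011"],
        endurance[endurance["event"] == "Moscow2013"],
        config.strata,
    )
    comparison_table = comparison.results_to_frame(results)
    if not comparison_table.empty:
        prevalence_table = prevalence_table.merge(
            comparison_table[["stratum", "ks_p_adj", "cvm_p_adj"]],
            on="stratum", how="left",
        )

    reference_curves = pd.DataFrame(
        {"grid": refs.grid, "F_clean": refs.F_clean, "F_dope": refs.F_dope}
    )

    paths: dict = {"country_map": country_map}
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in (
            ("cohort", df),
            ("prevalence", prevalence_table),
            ("comparisons", comparison_table),
            ("reference_curves", reference_curves),
        ):
            path = outdir / f"{name}.csv"
            table.to_csv(path, index=False, float_format="%.6f")
            paths[name] = str(path)
    return PipelineReport(
        cohort=df,
        prevalence_table=prevalence_table,
        comparison_table=comparison_table,
        reference_curves=reference_curves,
        paths=paths,
    )
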