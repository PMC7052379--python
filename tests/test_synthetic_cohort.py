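import numpy as np
import pytest

import hemoprev as hp
from hemoprev.records import PRIMARY_VARIABLES
from hemoprev.synthetic_cohort import (
    ALTITUDE_PROPORTIONS,
    ETHNICITY_BY_CONTINENT,
    CohortConfig,
    resolve_prevalence,
)


class TestConfigValidation:
    def test_bad_proportions_name_the_mapping(self):
        with pytest.raises(hp.ConfigError, match="sex_prop"):
            CohortConfig(sex_prop={"M": 0.6, "F": 0.6})

    def test_prevalence_outside_unit_interval(self):
        with pytest.raises(hp.ConfigError, match="prevalence"):
            CohortConfig(prevalence={"all": 1.5})

    def test_kappa_below_one(self):
        with pytest.raises(hp.ConfigError, match="kappa"):
            CohortConfig(doping_effect=hp.DopingEffect(kappa=0.8))

    def test_yaml_roundtrip_overrides_defaults(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text(
            "n_daegu: 10\nn_moscow: 5\n"
            "prevalence: {all: 0.5}\n"
            "doping_effect: {delta_abps: 2.0, kappa: 1.1}\n"
        )
        config = CohortConfig.from_yaml(path)
        assert (config.n_daegu, config.n_moscow) == (10, 5)
        assert config.doping_effect.delta_abps == 2.0
        assert config.sex_prop["Daegu2011"]["M"] == 0.53  # untouched default


class TestGenerateCohort:
    def test_default_cohort_size(self):
        config = CohortConfig(seed=1)
        records = hp.generate_cohort(config)
        assert len(records) == 3683
        events = [r.event for r in records]
        assert events.count("Daegu2011") == 1808
        assert events.count("Moscow2013") == 1875

    def test_zero_prevalence_all_clean(self):
        records = hp.generate_cohort(CohortConfig(n_daegu=500, n_moscow=500, prevalence={}, seed=2))
        assert all(r.doped is False for r in records)

    def test_seed_determinism(self):
        a = hp.generate_cohort(CohortConfig(n_daegu=200, n_moscow=200, seed=3))
        b = hp.generate_cohort(CohortConfig(n_daegu=200, n_moscow=200, seed=3))
        assert a == b

    def test_records_satisfy_invariants(self, small_cohort):
        for record in small_cohort[::37]:
            record.validate()

    def test_composition_recovers_configured_proportions(self):
        config = CohortConfig(n_daegu=100_000, n_moscow=0, prevalence={}, seed=4)
        df = hp.cohort_to_frame(hp.generate_cohort(config))
        assert (df["sex"] == "M").mean() == pytest.approx(0.53, abs=0.01)
        for cls, p in config.age_prop["Daegu2011"].items():
            assert (df["age_class"] == cls).mean() == pytest.approx(p, abs=0.01)
        for cont, p in config.continent_prop["Daegu2011"].items():
            assert (df["continent"] == cont).mean() == pytest.approx(p, abs=0.01)
        assert df["endurance"].mean() == pytest.approx(0.31, abs=0.01)
        for t, p in config.sampling_time_prop.items():
            assert (df["sampling_time"] == t).mean() == pytest.approx(p, abs=0.01)

    def test_mixture_truth_per_stratum(self):
        config = CohortConfig(
            n_daegu=40_000, n_moscow=0,
            prevalence={"Daegu2011:endurance": 0.3, "Daegu2011:non_endurance": 0.05},
            seed=5,
        )
        df = hp.cohort_to_frame(hp.generate_cohort(config))
        assert df.loc[df["endurance"], "doped"].mean() == pytest.approx(0.3, abs=0.02)
        assert df.loc[~df["endurance"], "doped"].mean() == pytest.approx(0.05, abs=0.01)

    def test_moscow_bias_removed_by_correction(self):
        """Raw values of the second event embed the inverse of the correction."""
        config = CohortConfig(n_daegu=5000, n_moscow=5000, prevalence={}, seed=6)
        df = hp.cohort_to_frame(hp.generate_cohort(config))
        corrected = hp.correct_cohort(df)
        corrected["abps"] = hp.score_cohort(corrected)
        means = corrected.groupby("event")["abps"].mean()
        assert means["Moscow2013"] == pytest.approx(means["Daegu2011"], abs=0.07)

    def test_prevalence_stratum_resolution_specific_first(self):
        prev = {"Daegu2011:endurance:F": 0.4, "Daegu2011:endurance": 0.2, "all": 0.1}
        assert resolve_prevalence(prev, "Daegu2011", True, "F") == 0.4
        assert resolve_prevalence(prev, "Daegu2011", True, "M") == 0.2
        assert resolve_prevalence(prev, "Moscow2013", False, "M") == 0.1
        assert resolve_prevalence({}, "Moscow2013", False, "M") == 0.0


class TestAssignEthnicity:
    def test_europe_always_caucasian(self):
        rng = np.random.default_rng(0)
        assert all(hp.assign_ethnicity("Europe", rng) == "Caucasian" for _ in range(50))

    def test_ncc_america_frequencies(self):
        rng = np.random.default_rng(1)
        draws = [hp.assign_ethnicity("NCCAmerica", rng) for _ in range(5000)]
        freq = {e: draws.count(e) / 5000 for e in ("Caucasian", "Asian", "African", "Oceanian")}
        assert freq["Caucasian"] == pytest.approx(0.48, abs=0.03)
        assert freq["Asian"] == pytest.approx(0.07, abs=0.02)
        assert freq["African"] == pytest.approx(0.45, abs=0.03)
        assert freq["Oceanian"] == 0.0

    def test_vectors_are_probability_distributions(self):
        for continent, vec in ETHNICITY_BY_CONTINENT.items():
            assert sum(vec) == pytest.approx(1.0, abs=1e-9), continent

    def test_unknown_continent(self):
        with pytest.raises(hp.DomainError):
            hp.assign_ethnicity("Atlantis", np.random.default_rng(0))


class TestAssignAltitude:
    def test_daegu_endurance_frequencies(self):
        rng = np.random.default_rng(2)
        draws = [hp.assign_altitude(True, "Daegu2011", rng) for _ in range(5000)]
        for cls, p in zip(("lt1000", "a1000_1500", "a1500_2000", "gt2000"), (0.5, 0.2, 0.2, 0.1)):
            assert draws.count(cls) / 5000 == pytest.approx(p, abs=0.03)

    def test_moscow_endurance_vector_sums_to_one_exactly(self):
        assert sum(ALTITUDE_PROPORTIONS[("Moscow2013", True)]) == pytest.approx(1.0, abs=1e-9)

    def test_moscow_endurance_frequencies(self):
        rng = np.random.default_rng(3)
        draws = [hp.assign_altitude(True, "Moscow2013", rng) for _ in range(5000)]
        assert draws.count("lt1000") / 5000 == pytest.approx(0.5329, abs=0.03)


class TestDopingEffect:
    def test_requires_doped_record(self, reference_record):
        with pytest.raises(hp.DomainError):
            hp.apply_doping_effect(reference_record.replace(doped=False))

    def test_null_effect_leaves_record_unchanged(self, reference_record):
        record = reference_record.replace(doped=True, HGB=15.6, MCH=10 * 15.6 / 5, MCHC=100 * 15.6 / 45)
        out = hp.apply_doping_effect(record, hp.DopingEffect(delta_abps=0.0, kappa=1.0))
        for var in PRIMARY_VARIABLES:
            assert getattr(out, var) == pytest.approx(getattr(record, var), abs=1e-9)

    def test_identities_hold_after_perturbation(self, reference_record):
        out = hp.apply_doping_effect(reference_record.replace(doped=True))
        out.validate()

    def test_score_moves_in_doping_direction(self, reference_record):
        out = hp.apply_doping_effect(reference_record.replace(doped=True))
        assert hp.compute_abps(out) > hp.compute_abps(reference_record)
        # rhEPO microdose direction: red-cell mass up, RET% suppressed (OFF-state)
        assert out.HGB > reference_record.HGB
        assert out.RET_pct < reference_record.RET_pct

    def test_monte_carlo_calibration_of_mean_shift(self):
        """Population mean score shift of doped records matches delta_abps."""
        config = CohortConfig(n_daegu=20_000, n_moscow=0, prevalence={"all": 0.5}, seed=7)
        df = hp.cohort_to_frame(hp.generate_cohort(config))
        df["abps"] = hp.score_cohort(df)
        adjusted = hp.adjust_scores(df, hp.default_model().without("Moscow"))
        doped = df["doped"].to_numpy()
        shift = adjusted[doped].mean() - adjusted[~doped].mean()
        assert shift == pytest.approx(config.doping_effect.delta_abps, abs=0.1)
        ratio = adjusted[doped].std() / adjusted[~doped].std()
        assert ratio == pytest.approx(config.doping_effect.kappa, abs=0.1)


class TestCohortCsv:
    def test_roundtrip(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        hp.write_cohort_csv(small_cohort[:20], path)
        df = hp.read_cohort_csv(path)
        assert len(df) == 20
        back = hp.frame_to_cohort(df)
        assert back[0].athlete_id == small_cohort[0].athlete_id
        assert back[0].HGB == pytest.approx(small_cohort[0].HGB)
        assert back[0].doped == small_cohort[0].doped
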