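import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import hemoprev as hp
from hemoprev.prevalence import GridSpec, score_contributions


class TestEmpiricalCdf:
    def test_single_score(self):
        assert hp.empirical_cdf([2.0], [3.0])[0] == 1.0
        assert hp.empirical_cdf([2.0], [1.0])[0] == 0.0

    def test_half(self):
        assert hp.empirical_cdf([0.0, 1.0], [0.5])[0] == 0.5

    def test_ties_counted_right_continuously(self):
        assert hp.empirical_cdf([1.0, 1.0, 2.0], [1.0])[0] == pytest.approx(2 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(hp.DataError):
            hp.empirical_cdf([], [0.0])

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=30))
    def test_bounds_and_monotonicity(self, scores):
        grid = np.linspace(-6, 6, 101)
        F = hp.empirical_cdf(scores, grid)
        assert np.all(np.diff(F) >= 0)
        assert F[0] == 0.0 or min(scores) <= grid[0]
        assert F[-1] == 1.0


class TestBuildReferenceCdfs:
    def test_identical_samples_give_identical_curves(self):
        x = np.arange(10.0)
        refs = hp.build_reference_cdfs(x, x.copy())
        assert np.array_equal(refs.F_clean, refs.F_dope)

    def test_grid_endpoints_cover_zero_and_one(self):
        refs = hp.build_reference_cdfs([0.0, 1.0], [2.0, 3.0])
        assert refs.F_clean[0] == 0.0 and refs.F_clean[-1] == 1.0
        assert refs.F_dope[0] == 0.0 and refs.F_dope[-1] == 1.0

    def test_step_mode_counting_oracle(self):
        refs = hp.build_reference_cdfs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], grid=[2.0])
        assert refs.F_clean[0] == pytest.approx(2 / 3)

    def test_kernel_mode_is_a_cdf(self):
        rng = np.random.default_rng(0)
        refs = hp.build_reference_cdfs(
            rng.normal(size=500), rng.normal(1.5, 1.2, size=500), smooth=True
        )
        assert refs.mode == "kernel"
        assert np.all(np.diff(refs.F_clean) >= -1e-12)
        assert refs.F_clean[0] < 0.01 and refs.F_clean[-1] > 0.99

    def test_stochastic_dominance_under_positive_delta(self, default_refs):
        assert np.all(default_refs.F_dope <= default_refs.F_clean + 1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(hp.DataError):
            hp.build_reference_cdfs([], [1.0])


class TestSimulateReferencePopulation:
    def test_doping_shifts_mean_by_delta(self, reference_model):
        clean = hp.simulate_reference_population(reference_model, None, False, 100_000, 1)
        dope = hp.simulate_reference_population(reference_model, None, True, 100_000, 2)
        assert dope.mean() - clean.mean() == pytest.approx(reference_model.delta, abs=0.02)
        assert dope.std() / clean.std() == pytest.approx(reference_model.kappa, abs=0.02)

    def test_female_effect_shifts_mean(self, reference_model):
        male = hp.simulate_reference_population(reference_model, None, False, 100_000, 3)
        female = hp.simulate_reference_population(reference_model, ["Female"], False, 100_000, 3)
        assert female.mean() - male.mean() == pytest.approx(-0.71, abs=0.02)

    def test_null_doping_node_indistinguishable(self):
        model = hp.ReferenceModel(delta=0.0, kappa=1.0)
        clean = hp.simulate_reference_population(model, None, False, 2000, 4)
        dope = hp.simulate_reference_population(model, None, True, 2000, 5)
        assert stats.ks_2samp(clean, dope).pvalue > 0.01

    def test_reproducible_given_seed(self, reference_model):
        a = hp.simulate_reference_population(reference_model, None, False, 100, 6)
        b = hp.simulate_reference_population(reference_model, None, False, 100, 6)
        assert np.array_equal(a, b)


class TestEstimatePrevalence:
    def test_clean_reference_maps_to_zero(self, default_refs):
        assert hp.estimate_prevalence(default_refs.F_clean, default_refs) == pytest.approx(0.0, abs=1e-12)

    def test_doped_reference_maps_to_one(self, default_refs):
        assert hp.estimate_prevalence(default_refs.F_dope, default_refs) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("pi", [0.0, 0.1, 0.3, 0.5, 0.9, 1.0])
    def test_mixture_identity_exact(self, default_refs, pi):
        """Convex combinations of the reference curves return pi to 1e-12."""
        F = pi * default_refs.F_dope + (1 - pi) * default_refs.F_clean
        assert hp.estimate_prevalence(F, default_refs) == pytest.approx(pi, abs=1e-12)

    def test_no_discriminative_power_is_error(self):
        grid = np.linspace(-3, 3, 50)
        F = hp.empirical_cdf([0.0], grid)
        refs = hp.ReferenceCDFs(grid=grid, F_clean=F, F_dope=F)
        with pytest.raises(hp.EstimationError):
            hp.estimate_prevalence(F, refs)

    def test_upward_shift_never_decreases_estimate(self, default_refs, reference_model):
        scores = hp.simulate_mixture_scores(0.2, 300, reference_model, seed=7)[0]
        base = hp.estimate_prevalence_from_scores(scores, default_refs)
        for shift in (0.01, 0.1, 0.5, 1.0):
            shifted = hp.estimate_prevalence_from_scores(scores + shift, default_refs)
            assert shifted >= base - 1e-12
            base = shifted

    def test_estimator_consistency_at_moderate_n(self, default_refs, reference_model):
        """MAE of the estimate over 200 seeded cohorts of n=600 stays < 0.03."""
        estimates = hp.replicate_mixture_estimates(
            0.2, 600, 200, default_refs, reference_model, seed=8
        )
        assert np.mean(np.abs(estimates - 0.2)) < 0.03


class TestBootstrap:
    def test_degenerate_data_zero_width(self, default_refs):
        low, high = hp.bootstrap_ci([0.5] * 40, default_refs, n_boot=200, seed=1)
        assert low == high

    def test_contributions_linearity(self, default_refs, reference_model):
        """The estimate equals the mean of per-score contributions exactly."""
        scores = hp.simulate_mixture_scores(0.3, 150, reference_model, seed=2)[0]
        c = score_contributions(scores, default_refs)
        direct = hp.estimate_prevalence_from_scores(scores, default_refs)
        assert c.mean() == pytest.approx(direct, abs=1e-10)

    def test_fast_path_matches_naive_resampling(self, default_refs, reference_model):
        scores = hp.simulate_mixture_scores(0.3, 80, reference_model, seed=3)[0]
        rng = np.random.default_rng(9)
        idx = rng.integers(0, 80, size=(50, 80))
        naive = np.array(
            [hp.estimate_prevalence_from_scores(scores[i], default_refs) for i in idx]
        )
        c = score_contributions(scores, default_refs)
        fast = c[idx].mean(axis=1)
        assert np.allclose(naive, fast, atol=1e-10)

    def test_interval_brackets_estimate(self, default_refs, reference_model):
        scores = hp.simulate_mixture_scores(0.2, 250, reference_model, seed=4)[0]
        est = hp.estimate_stratum(scores, default_refs, n_boot=500, seed=5)
        assert est.ci_low <= est.estimate <= est.ci_high

    def test_clean_sample_estimates_straddle_zero(self, default_refs, reference_model):
        """A doping-free population yields ~0 with negative CI bounds possible."""
        estimates = hp.replicate_mixture_estimates(
            0.0, 250, 100, default_refs, reference_model, seed=6
        )
        assert np.mean(estimates) == pytest.approx(0.0, abs=0.02)
        assert (estimates < 0).any() and (estimates > 0).any()
        scores = hp.simulate_mixture_scores(0.0, 250, reference_model, seed=7)[0]
        low, high = hp.bootstrap_ci(scores, default_refs, seed=8)
        assert low < 0 < high


class TestPosterior:
    def test_null_prior(self):
        f = stats.norm(0, 1).pdf
        assert hp.posterior_doping_probability(1.0, f, f, 0.0) == 0.0

    def test_uninformative_likelihood_returns_prior(self):
        f = stats.norm(0, 1).pdf
        assert hp.posterior_doping_probability(0.3, f, f, 0.4) == pytest.approx(0.4)

    def test_bayes_rule_hand_value(self):
        f_clean = lambda s: np.full_like(np.asarray(s, float), 0.2)
        f_dope = lambda s: np.full_like(np.asarray(s, float), 0.6)
        assert hp.posterior_doping_probability(0.0, f_clean, f_dope, 0.5) == pytest.approx(0.75)

    def test_both_densities_zero_is_nan(self):
        zero = lambda s: np.zeros_like(np.asarray(s, float))
        assert np.isnan(hp.posterior_doping_probability(0.0, zero, zero, 0.5))

    def test_invalid_prior(self):
        f = stats.norm(0, 1).pdf
        with pytest.raises(hp.DomainError):
            hp.posterior_doping_probability(0.0, f, f, 1.5)


class TestGridSpec:
    def test_default_grid_covers_pooled_range_with_pad(self):
        grid = GridSpec().make(np.array([0.0, 2.0]), np.array([5.0]))
        assert grid.size == 2001
        assert grid[0] == pytest.approx(-1.0)
        assert grid[-1] == pytest.approx(6.0)
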