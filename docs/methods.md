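# Methods

## The estimand and the estimator

The quantity of interest is the fraction π of athletes in a tested
population whose blood profile is drawn from a "doped" score distribution
rather than a "clean" one. The observed adjusted-score sample is modeled as
a two-component mixture

    F_emp = π·F_dope + (1−π)·F_clean,

where F_clean and F_dope are reference CDFs produced by a generative model of
the score. Integrating the mixture identity over the score axis gives the
area-ratio estimator

    π̂ = ∫(F_clean − F_emp) dx / ∫(F_clean − F_dope) dx,

evaluated by trapezoidal quadrature on a shared grid (2001 equally spaced
points spanning the pooled reference range ±1 score unit; signed trapezoidal
integration keeps the mixture identity exact at grid level, which the test
suite verifies to 1e-12). Signed differences are integrated where curves cross;
this is what makes the estimator linear in F_emp and hence unbiased for
mixtures. Negative estimates are legitimate output (a sample cleaner than
the clean reference); report tables floor the displayed point estimate at
0.00 while retaining the raw value in machine-readable columns.

Because the estimator is linear in F_emp, the estimate of a sample is the
mean of per-score contributions c(x_i); the percentile bootstrap resamples
those contributions directly, which makes 1000-replicate intervals cheap and
is verified against the naive resample-and-re-estimate loop to 1e-10.

## The reference model

Scores are Gaussian given covariates. An individual's mean is

    μ_i = μ0 + Σ_k β_k·1{level k active} (+ δ if doped),

with spread σ (·κ if doped). Defaults: μ0 = 0, σ = 1 (score units), doping
mean shift δ = 1.5 and spread inflation κ = 1.2, chosen once so the two
reference curves are separated comparably to the published reference-CDF
figure (their horizontal gap, A₂ = δ, is the discriminative power of the
score). The β_k are the packaged adjustment coefficients, including the sex
correction (Female −0.71). Reference populations use 10⁵ draws per arm,
large enough that Monte-Carlo noise in the curves is below grid resolution.
Both step-ECDF and Gaussian-kernel (Silverman bandwidth) reference curves
are available; the step mode is the default and the mode is recorded in the
output.

Posterior doping probabilities for an individual score use Bayes' rule over
the clean/doped densities with a supplied prior; where both densities vanish
the posterior is undefined and NaN is returned.

## Covariate adjustment

A simple linear model (OLS) of the score on indicators for Female, age <20
and >30, afternoon/evening sampling, five continents and the second event;
reference condition: male, age 20–30, morning, Europe, first event.
Adjustment subtracts the coefficients of a record's active levels, mapping
every record to the reference condition. CIs are coefficient ± 1.96·SE.
Adjustment is intentionally not idempotent for non-reference records; the
pipeline applies it exactly once.

Two age stratifications coexist in the problem: cohort composition is
described by classes ≤19 / 19–24 / ≥25, while the adjustment model uses
<20 / >30. Records therefore carry both a class and a numeric age; the
generator draws the age inside the class, and the model builds its
indicators from the numeric age. The discrepancy between the two
stratifications is inherited from the study design and left unresolved.

## Event offset: one bias, two removal routes

The second event shows a systematic non-biological offset. It can be removed
in exactly one of two ways, and the pipeline config makes the choice
structural:

* **variable scale** (default): add the pre-analytical factors (HGB −0.3,
  HCT −0.7, RBC −0.08, RET% +0.07) to the second event's primary variables
  before scoring, then disable the event coefficient during adjustment;
* **score scale**: leave the variables alone and subtract the event
  coefficient (−0.16) during adjustment.

Applying both would double-correct. The synthetic generator embeds the bias
once, at variable scale, as the exact inverse of the printed correction, so
the variable route recovers comparability exactly (verified in tests). Note
a sign tension inherited from the source material: the printed additive
factors, taken literally, induce a score-scale offset of about +0.43 under
the default surrogate weights, while the printed score-scale event
coefficient is −0.16. Within this package the two routes are each
self-consistent (the score route should be used with `adjustment_mode:
refit`, which absorbs whatever offset the data actually carry), but the two
printed constants cannot both be images of the same bias under the default
surrogate score; users supplying real ABPS values should prefer the variable
route, which is the one the printed factors define operationally.

## The surrogate score

The original ABPS classifier is proprietary; the package ships a transparent
linear surrogate over standardized variables,

    score = (1/√7) Σ_j w_j (x_j − m_j)/s_j,

with default weights +1 (HGB, HCT, RBC), −1 (RET%), +0.25 (MCV, MCH, MCHC),
reference means/spreads at the clean baseline. It is strictly increasing in
HGB and decreasing in RET%, which is the qualitative behavior the pipeline
needs; every downstream stage is score-agnostic and real ABPS values in the
input CSV bypass the surrogate.

## The synthetic cohort generator

The generator emulates the study's data structure, not athlete physiology:

* cohort sizes 1808 + 1875 and the published per-event composition of sex,
  age class, continent, endurance share; sampling time defaults to
  (0.5, 0.3, 0.2) for morning/afternoon/evening, a plausible allocation the
  source never specifies;
* ethnicity imposed per continent (Europe all Caucasian, …, South America
  ¼ each — including the odd ¼ "Oceanian", reproduced as printed); altitude
  allocation per event and discipline group as printed (one vector prints as
  summing to 0.9999 and is normalized at draw time; the published Moscow
  continent column sums to 0.99 and the stored default is renormalized);
* hematology baselines (HGB 15.2 ± 0.9 g/dL, HCT 45 ± 2.5 %, RBC 5 ± 0.3
  10⁶/µL, RET% 1.2 ± 0.25) are arbitrary-but-plausible configuration
  defaults for a clean morning European male reference, not claims about the
  real cohort;
* covariate and doping effects are stated on the score scale and mapped to
  the variable scale through the numeric gradient of the surrogate at the
  baseline means. This calibration is first-order: curvature of the
  derived-index ratios leaves a residual bias of ~0.01–0.03 score units on
  δ = 1.5, well inside the Monte-Carlo contract tolerance (0.1) the tests
  enforce. The doped direction raises HGB/HCT/RBC and, by default, lowers
  RET% (OFF-state; configurable to the ON-state);
* doped records inflate the noise of the primary variables by κ; Gaussian
  noise that would produce a nonpositive value is redrawn (truncation mass
  <0.2% in the worst stratum, mean effect <1e-3);
* smoking and illness are fixed at healthy non-smoker; there are no fields
  for them.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: within-athlete longitudinal structure (one test
per athlete per event), non-Gaussian or skewed marginals, correlated
measurement error between variables, country-level effect heterogeneity
beyond continent effects, and any pharmacokinetics of actual rhEPO use. The
generator defines ground truth for the *estimator*, not a physiological
simulation of doping.

## Statistical comparisons

Between-event comparisons apply the two-sample Kolmogorov–Smirnov and
Cramér–von Mises tests to adjusted score samples per stratum (all / sex /
country). Distribution mode is the default reading of "the two curves";
comparing score distributions is the well-defined operation, and both tests
are rank-based, so any monotone rescaling of the score leaves them
unchanged. Asymptotic p-values are used (effective size n·m/(n+m)); tests
agree with 1000-permutation p-values within 0.02 at n = 30 and hold their 5%
level within [0.03, 0.07] in 1000-stratum null calibrations. The KS and CvM
p-value families are Benjamini–Hochberg-adjusted separately across strata.
Strata need ≥10 athletes per event (≥7 for female-only strata) to enter the
comparison; per-country prevalence cells with fewer than 5 athletes are left
blank. All thresholds are configurable.

## Numerical and reporting choices

* Grid: 2001 points, ±1 pad; estimator error from grid discretization is
  below 1e-3 for the default models.
* Countries are anonymized to "Country A, B, …" in outputs (sorted label
  order).
* Deduplication keeps the earliest record per athlete per event (stable
  sort; ties keep file order).
* Endurance = running or walking disciplines of ≥800 m; relays, hurdles
  <800 m, jumps, throws and combined events are non-endurance.
* Sampling-time cut points (morning <12:00, afternoon 12:00–18:00, evening
  ≥18:00) are configurable; the source records collection from 07:05 to
  24:00 without defining cuts.
* All randomness flows through per-stage children of a single seed;
  pipeline outputs are byte-identical across reruns (fixed CSV float
  format).

## Problem sizes used in the packaged checks

Recovery studies average 200 cohorts per stratum at the published stratum
sizes (569/653/246/323) against 10⁵-draw reference arms; bootstrap coverage
uses 500 replicates of n = 250 with 1000 resamples each; null calibration
uses 1000 strata of 200 + 200 scores; the composition check generates 10⁵
records. These sizes put Monte-Carlo noise well inside each check's
tolerance while keeping the default suite fast.

## Known limitations

* The surrogate score is not the proprietary ABPS; absolute score values are
  not comparable to published ABPS values, only the pipeline's behavior is.
* The area-ratio estimator assumes the reference model is correctly located
  (μ0 aligned with the clean population mean); a location error of ε
  translates into a prevalence bias of ε/δ.
* Asymptotic test p-values are approximate below n ≈ 20 per arm; a
  permutation fallback is not built in (the minimum-n thresholds keep
  samples above the regime where the approximation is poor).
* Bootstrap percentile intervals undercover slightly near π = 0 where the
  estimator distribution is skewed; observed coverage at n = 250, π = 0.2 is
  ~93–95%.
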