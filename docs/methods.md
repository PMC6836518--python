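# Methods

This note documents the statistical models, the numerical choices and the
synthetic-data assumptions behind `bridgesurv`, and what the test suite does
and does not establish about real data.

## 1. Random-effects pooling of literature hazard ratios

Each published estimate enters as β = log(HR) with a variance reconstructed
from the lower 95% CI bound L:

    Var(β) = ((β − log L) / 1.96)²

Only the lower bound is used; when the published interval is asymmetric on
the log scale by more than 10% the reader emits a warning, since that
suggests the interval was not a Wald interval for log HR and the
reconstructed variance is approximate. The hierarchical model is

    βᵢ ~ Normal(δᵢ, Var(βᵢ)),   δᵢ ~ Normal(d, τ²),
    d ~ Normal(0, 10⁵),          τ² ~ Uniform[0, 10].

**Sampler.** A Gibbs scheme with three non-standard choices:

* *d* is updated from its **partially collapsed** conditional with the δᵢ
  marginalised out (βᵢ | d ~ N(d, Varᵢ + τ²), still conjugate normal). The
  naive conditional given δ degenerates as τ² → 0 — d and δ become glued
  together and the chain stops learning from the data — while the collapsed
  update mixes well at any τ². The δᵢ are redrawn immediately after d, which
  keeps the scheme a valid partially collapsed Gibbs sampler.
* τ² has a non-conjugate bounded-uniform prior; it is updated by **slice
  sampling** (stepping-out with shrinkage, restricted to (0, 10]). Given δ
  and d the conditional log-density reduces to
  −n/2·log τ² − Σ(δᵢ−d)²/(2τ²), a scalar function, so the update is cheap
  and needs no proposal tuning.
* Per-chain seeds are `seed + chain index`; chains start overdispersed
  (d jittered, τ² ~ U(0.05, 1)).

Defaults are 3 chains × 50,000 iterations with a 25,000-iteration burn-in.
The pooled hazard ratio is reported as exp(posterior mean of d) — the
convention the headline pooled estimates use — with exp(median) alongside,
and the 95% CrI is the equal-tailed interval of exp(d). All pooling happens
on the log scale; exp is applied only at the summary stage.

**Convergence.** R-hat is the classic between/within form
√(((n−1)/n·W + B/n)/W), floored at 1; fits flag R-hat > 1.1 (a common
working threshold). The test suite cross-checks against arviz's
rank-normalised split R-hat on well-mixed chains.

## 2. Weibull baseline from a grouped life table

The reference survival is S(t) = exp(−(t/σ)^k). A life table supplies
per-person-year death rates m for 5-year bands [a, b); each band is
converted to a conditional death probability q = 1 − exp(−m·(b−a)) and, when
counts are absent, given a fixed pseudo-population of 100,000 so bands weigh
equally. The fit maximises the per-band left-truncated binomial likelihood

    Σ_k  d_k log q_k(θ) + (N_k − d_k) log(1 − q_k(θ)),
    q_k(θ) = 1 − S(b_k)/S(a_k).

Conditioning each band on survival to its own start is the standard grouped
interval-censored form; it makes the fit exactly invariant to bands below
the fitting floor, which is how the >45-year restriction is implemented
(bands below `fit_min_age`, default 45, are simply excluded — the usual age
range of the target disease). A formulation that conditions every band on
survival to the floor instead would reward parameter values that push
survival between the floor and the band start toward 1, because deaths
before a band's start are never counted against that band; the per-band
binomial has no such bias and recovers the generating parameters exactly on
noiseless tables. An open-ended final band (age_hi = ∞) carries no interval
information under this likelihood and is skipped.

Optimisation is Nelder–Mead on (log k, log σ) from three starts
(k ∈ {1, 5, 8}); the exponential special case k = 1 is recovered for
constant-hazard tables.

## 3. Multiplicative hazard model and simulation

The patient-level log relative hazard is η = Σ β_c·x_c over the active
covariate subset: presence indicators for dysphagia, falls, wheelchair use
and aspiration pneumonia, and the walking-distance term per metre of
*deficit* Δ6MWD = reference(age, sex) − patient distance (signed by default,
so an unusually fit patient gets HR < 1; flooring at 0 is a flag). The
individual intercept is not a free parameter: baseline risk is anchored to
the sex-matched Weibull curve left-truncated at the patient's age. Adjusted
survival is [S(t)/S(a₀)]^{exp(η)} and death times are drawn by inverting
that CDF:

    t = σ·[(a₀/σ)^k − log U / HR]^{1/k},  U ~ Uniform(0, 1).

For a Weibull baseline the hazard multiplication is identical to an
accelerated-failure-time rescaling of time by HR^{−1/k}; the tests assert
this equivalence numerically. When coefficients carry posterior samples,
every simulated patient draws one coefficient vector, so downstream
intervals mix parameter uncertainty with covariate variability.

## 4. Synthetic cohorts

The cross-sectional dataset that informed the real covariate distributions
is not public, so `CohortSpec` defaults are **synthetic placeholders**: age
~ N(67, 9²) truncated at 45 y; 55% male; heights N(175, 7²)/N(162, 6²) cm;
weight and 6MWD from linear regressions (see the dataclass for the
coefficients) with normal residuals; falls prevalence 0.35; dysphagia 0.50
via a zero-inflated 0–10 swallowing score (point mass at 0 of size
1 − prevalence, presence = score ≥ 1, which reproduces the dichotomisation
rule exactly); lower-body severity multinomial (0.45, 0.35, 0.20) with
"severe" — and only "severe" — implying wheelchair use, which in turn forces
the recorded walking distance to 0; aspiration pneumonia Bernoulli with 1%
baseline prevalence multiplied by a published risk ratio of 9.1 given
dysphagia. Reference walking norms are sex-specific age-band normals
(means 620→400 m for men, 580→360 m for women across 45–85+, sd 85 m),
synthetic values in the range healthy-adult norms occupy.

Two anchors calibrate these defaults, fixed once: the cohort is elderly
(>45) and the median walking deficit versus the reference norms is ≈281 m
(the 6MWD regression intercept of 473 m was set by a one-off large-sample
calibration run and then frozen). Everything else is a modelling choice, so
passing tests demonstrate internal consistency of the generator and the
estimators — prevalence concentration, invariant enforcement, structural
wheelchair/6MWD anticorrelation — not agreement with any real patient
population. The generator also omits features real data would have:
measurement error in the swallowing score, correlated comorbidity,
longitudinal progression, and informative missingness.

## 5. Model selection and validation

Candidates are all 32 subsets of the five predictors (a stepwise-forward
mode restricted to supersets of a seed model is available; full enumeration
is the default). For each candidate and a validation study (n, median
follow-up, observed death % with CI, age/sex mix), 500 replicate cohorts of
the study's size are generated; each patient's death within the follow-up
horizon is a Bernoulli draw against the adjusted survival, and the replicate
records the percent dying. Follow-up is fixed at the study median for every
patient. The predicted CrI is the equal-tailed 95% interval over replicates;
coverage uses a closed interval. Ranking is: covered first, then smaller
|median predicted − observed| (ties within 1 percentage point — below
replicate Monte-Carlo noise at default settings — resolved toward the
smaller model), then size. Where several validation studies exist the first
row of the studies file is the reference; short-follow-up studies with
heterogeneous follow-up distributions are best left out of selection and
used descriptively.

## 6. Excess mortality and years of life lost

For each of n = 10,000 virtual patients the disease log-hazard λ and a
matched reference log-hazard λ* (same age, sex, height, weight; no
dysphagia, falls or aspiration pneumonia; zero walking deficit) are computed
under one coefficient draw, giving HR = exp(λ − λ*). The summary is the
median and the equal-tailed 95% **prediction** interval of the per-patient
HRs — prediction rather than credible, because the interval deliberately
mixes covariate variability with coefficient uncertainty — plus the fraction
of patients with HR > 1.

Years of life lost integrate conditional survival by composite Simpson with
a 0.1-year grid from the patient's age to the age where the baseline
survival is numerically zero (cumulative hazard 37, S ≈ 10⁻¹⁶). A fixed
calendar cap would silently truncate tail mass for light-hazard baselines —
for an exponential with 30-year residual mean, a 120-year cap loses about
half a year — whereas the survival-based limit keeps the quadrature error
below 0.1 year for any Weibull baseline (a grid-size guard handles
heavy-tailed shape < 1 cases). The reported YLL is the median over patients
of residual lifetime at HR = 1 minus residual lifetime at the patient's HR.

## 7. Reproducibility and problem sizes

One master seed drives everything; the pipeline derives per-stage seeds by
hashing `seed:stage` (kept below 2³¹) and each stage's JSON embeds its seed,
settings and input hashes so stages re-run standalone identically. The test
suite and the acceptance script use deliberately moderate problem sizes —
10,000-iteration chains for recovery studies, 10⁵ draws for Monte-Carlo
oracles, 3,000 patients for YLL integration, 500-replicate selection runs —
chosen so the full suite completes in well under a minute of compute per
module while keeping Monte-Carlo error far below the asserted tolerances.

## Known limitations

* The meta-analysis variance reconstruction trusts the published lower CI
  bound; asymmetric intervals (e.g. from profile likelihoods) are flagged
  but not corrected.
* The hazard model assumes proportional hazards with time-constant
  covariates — no progression, no competing risks, no frailty.
* Binary predictors discard severity gradations (dysphagia is any score ≥ 1).
* The reference population implicitly contains diseased individuals, which
  biases the excess-HR estimate toward the null; no correction is applied.
* Absolute mortality levels depend entirely on the supplied life table; the
  synthetic Weibull-derived tables used in examples and tests are not a
  national life table, and null-model percentages computed from them are
  illustrative, not estimates.
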