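# Methods

This package implements a two-study analysis of multifactorial reading-skill
risk, exercised end to end on synthetic cohorts so every result is
reproducible from code alone.

## The decision model

Motion-discrimination behaviour is modelled as a drift diffusion process:
on each trial a noisy decision variable starts at `z = z_rel * a`, drifts at
rate `v_c` (one rate per stimulus coherence c in {6, 12, 24, 48}%), and
diffuses with unit coefficient until it is absorbed at `a` (correct, with
accuracy coding) or 0 (error). Reaction time is the first-passage time plus
a non-decision component `t_nd`. Across trials, drift is
Normal(`v_c`, `s_v`^2), the starting point Uniform over a range `s_z`, and
non-decision time Uniform over a range `s_t`. With left/right motion
symmetric, `z_rel` is fixed at 0.5; `s_z` is variability around that
unbiased start. All parameters use the sigma = 1 scaling convention;
multiply `v`, `a`, `s_v`, `s_z` by 0.1 to convert to the sigma = 0.1
convention used by much of the older literature.

### Likelihood

The first-passage density uses the standard pair of series expansions for
the zero-drift unit-boundary process (a small-time expansion in image
charges and a large-time Fourier sine expansion), choosing per evaluation
whichever needs fewer terms for truncation error below 1e-7. The drift
dependence factors out as `exp(-v z - v^2 t / 2)`, so Gaussian across-trial
drift variability integrates in closed form; uniform `s_z` and `s_t` are
averaged by fixed 11-point Gauss-Legendre quadrature each. The full density
therefore reduces *exactly* to the shifted simple density when all
variabilities are zero. Per-trial densities are floored at 1e-10 inside the
likelihood so no single outlier dominates the objective. The kernels are
numba-compiled; total first-passage mass is conserved to better than 1e-4
across the plausible parameter range (tested).

### Fitting

Each subject's 240 analysis trials (valid 6-48% coherence trials) are fit
by penalized maximum likelihood over the nine free parameters
(v6, v12, v24, v48, a, t_nd, s_t, s_z, s_v) within the box
v in [0, 8], a in [0.3, 4], t_nd in [0.1, 1.5], s_t in [0, 0.8],
s_z in [0, 0.9 a], s_v in [0, 3]. Internally s_t is parameterized as a
fraction of `2 t_nd` and s_z as a fraction of `a`, so the support
constraints `t_nd - s_t/2 >= 0` and `s_z < a` are a fixed box and the
objective is smooth inside it. Ten starts (nine scrambled-Sobol points plus
one moment-based heuristic) are screened by raw objective value; bounded
Nelder-Mead polish runs from the best three, followed by an L-BFGS-B
refinement of the winner. Ties resolve to the lowest objective, then the
earliest start.

The objective adds a weak half-normal shrinkage term on s_v
(`0.5 (s_v / 0.8)^2`, i.e. sd 0.8; `FitConfig.s_v_shrinkage_sd`, set `None`
to disable). Rationale: the joint (v, s_v) likelihood has a well-known
ridge, and on a minority of 240-trial datasets the unpenalized optimum runs
to implausibly large s_v with proportionally inflated drift rates — we
verified on simulated data that such runaway optima can beat the generating
parameters by several nats, i.e. this is small-sample likelihood behaviour,
not an optimizer failure. The shrinkage (roughly: a prior belief that
across-trial drift sd beyond ~1.6 is implausible for this task) removes the
runaway solutions while costing ~0.3 nats at typical s_v values. Reported
`nll` is always the unpenalized data likelihood. With shrinkage, true vs
recovered Pearson r across 50 heterogeneous simulated subjects at 240
trials is >= 0.83 for every drift rate, ~0.96 for `a`, and ~0.97 for
`t_nd`; `s_z` and `s_v` recover poorly at this trial count (r ~ 0-0.5),
which is the expected weak identifiability of the variability parameters —
they are reported, not gated.

### Simulator

Trials are simulated by Euler-Maruyama integration at a 0.5 ms step with a
Brownian-bridge within-step crossing correction (without it, discrete
stepping misses intra-step boundary crossings and biases the first-passage
distribution at order sqrt(dt)). Decision times are capped at the task's
10 s response deadline; capped trials are flagged. Simulated and analytic
distributions agree to Kolmogorov distance < 0.01 at 10^6 trials across
parameter sets spanning the plausible range (tested; typical distance
~0.002-0.003, i.e. Monte-Carlo limited).

## Screening

The acceptable response window is 200 ms to 10 s, endpoints inclusive (the
window is given; endpoint handling is our convention). Subjects are
excluded, in order: (i) incomplete sessions (< 300 designed trials);
(ii) no evidence of above-chance performance, read as failing to exceed
60.5% accuracy at *every* one of the four analysis coherences; (iii) more
than 15% of designed trials outside the RT window (counting all designed
trials, including 100% coherence). The 60.5% constant is treated as given;
it is not re-derived from a binomial criterion. The 100% coherence
condition (where performance is non-monotonic in real data) is dropped from
analysis, leaving 240 of 300 trials. Reading skill is the mean of the two
standardized reading measures (WJ basic reading and TOWRE index); a
composite below 85 defines the dyslexic range, at/above 85 with no prior
diagnosis the control range, anything else Unlabeled. The per-subject
fast-error ratio is median(correct RT) / median(error RT) pooled over
coherences (per-coherence ratios are emitted as diagnostics); it is
undefined (NaN, flagged) for error-free subjects.

## Synthetic cohorts

**Cohort 1** (clinic-referred emulation): two groups (110 diagnosed, 105
control) drawn from a bivariate Gaussian on the standard-score scale
(mean 100, sd 15), separated by d = 0.93 on phonological awareness and
d = 0.81 on rapid naming, with within-group r(PA, RAN) = 0.45 — the
separations are published values; the correlation is our choice of a
realistic middling coupling between the two phonological dimensions. A
pseudoword-reading score is generated as a linear function of PA and RAN
(weights 0.35 each on the z scale) with optional planted age interactions
for calibration tests.

**Cohort 2** (psychophysics-study emulation, default n = 106): four
orthogonal standard-Gaussian latent factors — visual encoding, phonology +
nonverbal IQ, rapid naming, decision variability — map through a loading
matrix to 16 observed variables (9 DDM parameters, 6 phonological subtests,
nonverbal IQ), plus unique noise completing each variable's variance to 1.
Loadings (0.5-0.85) mirror the qualitative pattern the analyses probe:
drifts + s_v on factor 1, PA subtests + phonological memory + IQ on factor
2, the two rapid-naming subtests on factor 3, s_t + t_nd + s_z on factor 4,
and `a` loading on nothing (pure uniqueness). Standardized values are
affine-mapped to natural units (behavioral scores to mean 100/sd 15; DDM
parameters to task-plausible locations, e.g. a = 1.3 +/- 0.25,
t_nd = 0.45 +/- 0.07) and clipped into the valid parameter region (clips
counted and reported). Reading skill is a weighted factor sum
(0.30, 0.50, -0.40 sign conventions as stated in the code, decision
variability negative) plus a direct -0.25 path from `a`, with residual
noise completing unit variance; two reading tests add small independent
test noise (sd 3 points) before averaging. Each subject's full 300-trial
session is then simulated from their true DDM parameters (the 100%
coherence drift is set to 1.25 x v48, used only by the screening stage).

The **cascade variant** (`cascade_config()`) generates the alternative the
additive analysis must reject: a single sensory factor drives both the DDM
parameters and the phonological subtests, and reading is a function of
*observed* PA only (weight 0.7) — so DDM measures correlate with reading
marginally but carry no information beyond PA by construction.

What the generator does not emulate: age effects on any measure (age is an
independent covariate), test ceiling/floor effects, non-Gaussian score
distributions, RT contaminants (the simulated sessions are clean, so the
screening stage's exclusion rules are exercised by a dedicated
planted-violation cohort), and session-order effects. Passing tests
therefore show the *statistical machinery* behaves as claimed under the
planted structure, not that real data satisfy that structure.

**Planted-violation cohort**: 119 subjects of lightweight (non-DDM) trials
with exactly 5 incomplete sessions, 2 near-chance performers (42% accuracy,
safely under the 60.5% rule at n = 60 per coherence), and 6 subjects with
22% out-of-window responses; the screening stage must retain exactly 106.

## Statistical modelling

All continuous variables are z-scored before modelling (coefficients are
standardized); binary covariates enter as 0/1. Model selection is
exhaustive all-subsets by AIC with ties toward fewer parameters —
deterministic and reproducible. The median-RT model is a linear mixed model
(REML) with a subject random intercept and fixed effects of z-scored
coherence (entered linearly), age, and reading skill; a degenerate random
intercept triggers an OLS fallback with a flag. The DDM composites are
first principal components (v_comp over the four drifts + s_v; d_comp over
s_t, t_nd, s_z), unit-variance and sign-oriented to correlate positively
with the mean of their z-scored constituents. The additive model's DDM
block is tested by the nested F-test of PA + RAN + IQ against
PA + RAN + IQ + {v_comp, d_comp, a}. Correlation structure uses Pearson
correlations with Holm-Sidak step-down adjustment over the upper triangle
and Ward clustering on distance 1 - r (not 1 - |r|: positively correlated
blocks should merge first), cut at k = 3 by default. Lasso uses 10-fold CV
with a fixed shuffled-fold seed, selecting the CV-minimum penalty (not the
1-SE rule). Mediation is the product-of-coefficients estimate with a
percentile bootstrap (default 5000 resamples, seeded); for these linear
models total = direct + indirect exactly. The subgroup analysis z-scores
each drift over the *full* cohort before averaging and subsetting, so the
"mean drift" of a stratum is comparable across strata.

Classification (cohort 1) is quadratic discriminant analysis — per-class
Gaussian with its own covariance, empirical priors — evaluated by
leave-one-out cross-validation; near-singular class covariances are ridged
(reg 1e-6) before giving up. The accuracy CI is the normal-approximation
binomial interval. Effect sizes are pooled-SD Cohen's d, dis-attenuated by
dividing by the square root of the measure's test-retest reliability.

## Factor analysis

Retention combines the Kaiser rule with Horn's parallel analysis (95th
percentile of eigenvalues from 1000 random normal datasets of the same
shape; the retained count is the run of leading observed eigenvalues above
their thresholds). Extraction is maximum likelihood (statsmodels) with
varimax rotation; Heywood cases are floored at uniqueness 0.005 and
flagged. Factor scores use the regression (Thurstone) method,
`Z R^{-1} Lambda`. Per-factor explained variance is the rotated sum of
squared loadings divided by the number of variables (so the four-factor
total is the share of *total* variance the common factors reproduce).
Variables loading on no factor — by design, `a` — are characterized by
their uniqueness as a diagnostic. The LOO-CV comparison refits the
factor-score regression per held-out subject and reports
`1 - SSE/SST` for the full k-factor model and the single best factor.

## Problem sizes and numerical choices

The test suite and the acceptance script regenerate everything they
measure. Sizes used: mass conservation by adaptive quadrature (tolerance
1e-4); simulator/analytic Kolmogorov checks at 10^6 trials per parameter
set (5 sets); parameter recovery with 50 subjects at 60 trials per
coherence; classifier calibration at 2000 per class against the analytic
Bayes rate Phi(d/2); the additive-vs-cascade discrimination property at 50
replicates of n = 106 (run on the generator's true parameter tables — the
property under test is the model-selection behaviour, which is separable
from DDM estimation error); factor recovery at 20 replicates of n = 200
with 300-dataset parallel analysis inside each replicate (1000 in the
standalone analysis driver). Tucker congruence with Hungarian column
matching and sign alignment scores loading recovery.

## Known limitations

- `s_z` and `s_v` are weakly identified at 240 trials per subject; analyses
  that consume them do so through composites (d_comp, v_comp) where the
  shared variance, not the per-subject point estimate, carries the signal.
- The s_v shrinkage trades a small bias for ridge robustness; fits with
  `s_v` genuinely near 1.5+ will be pulled down.
- The generator's orthogonal-factor world is idealized; real cohorts have
  correlated factors, age structure, and non-Gaussian tails.
- The Euler simulator's bridge correction treats the two boundaries
  independently within a step; the residual error is far below the
  Monte-Carlo noise at the tested sizes but is not exactly zero.
- QDA LOO-CV refits per held-out point via sklearn; with empirical priors
  the held-out class balance shifts by one observation, a 1/n effect
  ignored here.
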