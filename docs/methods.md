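# Methods

## The problem

Laboratory acute stress tests (TSST, gTSST, SECPT, MAST and their
no-stress controls) measure salivary cortisol at a handful of timepoints
relative to stressor onset, and summarize each participant's response
with indicators: area under the cortisol–time curve with respect to
ground (AUCg) and increase (AUCi), reactivity (cortisol at the expected
peak minus baseline) and maximum increase (largest positive excursion
above baseline). Because these are computed directly from whatever
samples a study happened to collect, they inherit the study's sampling
schedule: AUCg in particular grows mechanically with sampling duration,
which biases any analysis that pools studies with different schedules.
`corticurve` addresses this by fitting a parametric response curve per
participant and computing all indicators from the fitted curve on a
common 1-minute grid over [0, 80] min, so that every participant's
indicators refer to the same time window regardless of when saliva was
actually sampled.

## The response-curve model

The structural response is a scaled gamma density plus baseline,

    g(t) = A · f(t − dT; α, β) + b0 + b1 · (t − dT),

with f the gamma density (shape α, rate β per minute), amplitude A
(nmol/L·min), baseline b0 (nmol/L), optional linear drift b1 (nmol/L per
min, a stand-in for the diurnal decline) and onset shift dT (min). The
density is defined as 0 for t − dT ≤ 0: the response starts at the
(possibly shifted) stressor onset, before which the curve is the
baseline-plus-drift line. The gamma shape captures the typical
rise-then-slower-recovery of a cortisol response; its known limitation
is that α controls skewness and kurtosis jointly, so the recovery slope
cannot vary independently of the rise.

Two estimation strategies with deliberately different bias–variance
trade-offs are provided.

### Amplitude scaling model (ASM)

Assumes one population shape; only the amplitude varies between
individuals. The population curve is fitted by pooled nonlinear least
squares (lmfit) on stress-condition responders only — participants whose
cortisol rises ≥ 1.5 nmol/L from the corrected baseline to the maximum
within 15–45 min — with b0 *fixed* to the sample's mean baseline rather
than estimated. Whether dT and b1 enter is decided by BIC
(k·ln N − 2·lnL with the profiled Gaussian likelihood, N the pooled
sample count); ties within 1e−9 go to the simpler model. Individual
curves then come from a three-step scaling: subtract the participant's
observed baseline, scale the unit-amplitude population shape to the
normalized values by ordinary least squares (closed form
A_i = Σ y_j f(t_j) / Σ f(t_j)², baseline sample excluded from the loss
since its normalized value is 0 and f(0) ≈ 0 for α > 1), and add the
observed baseline back. A_i is unconstrained in sign so that declining
control or non-responder profiles map to negative amplitudes.

### Multilevel model (MM)

A nonlinear mixed-effects model: each individual's parameter vector
scatters around population fixed effects, log-normally for the
positivity-constrained α, β, A and normally for b0, b1, dT (configurable).
Covariates act linearly on the transformed scale; the default retained
set is gender on A and b0, the control-condition dummy on A, b0, b1 and
dT, and the MAST dummy on β and b0, with TSST-stress as reference. The
residual model is "constant" (homoscedastic Gaussian).

Estimation is a Monte-Carlo EM targeting exact marginal maximum
likelihood:

- **E-step.** Per individual, the posterior mode of the random effects
  is found by a damped Gauss–Newton solver with analytic Jacobians,
  vectorized over all individuals sharing a sample count; the Laplace
  covariance at the mode seeds a Gaussian importance-sampling proposal
  (inflated 1.5×, 96 draws by default) from which posterior means,
  second moments and expected residuals are computed. The draws are
  common random numbers fixed at the start of the fit, so the whole EM
  is a deterministic fixed-point iteration given the seed.
- **M-step.** Fixed effects by (weighted) regression of posterior-mean
  parameters on the covariate design; random-effect variances from the
  posterior second moments; residual variance from the expected residual
  sum of squares. Parameters included without a random effect are
  updated by a pooled Gauss–Newton step.

A pure Laplace (joint-MAP) EM is available (`mc_samples=0`) and is exact
for models linear in their random effects — on that reduction the
estimator reproduces closed-form linear mixed-model ML, which the test
suite verifies against statsmodels MixedLM. For the nonlinear model the
MAP-only variant carries a small systematic fixed-effect bias (the
Laplace approximation does not vanish with more individuals when samples
per individual stay fixed), which is why the MC moments are the default.

Shrinkage is intrinsic: the Gaussian prior pulls individual estimates
toward the (covariate-adjusted) population mean, the harder the fewer or
noisier the individual's samples. Fixed-effect standard errors come from
the observed information of the importance-sampled marginal likelihood,
differentiated numerically over all fixed-effect coefficients jointly —
important because α and β form a likelihood ridge (they trade off while
preserving the peak location), making their marginal uncertainty much
larger than the naive √(ω/n). Covariate effects are retained per the
screening rule: p < .05, coefficient of variation (100·SE/|estimate|)
≤ 25%, and no BIC deterioration.

Applying a trained MM to new data re-estimates only the random effects
with the population parameters frozen (`estimate_individuals`), which is
how model-based indicators are produced for evaluation cohorts the model
never saw.

## Indicators

Observation-based (OBS) indicators use the raw samples: trapezoidal AUCg,
AUCi = AUCg − c(0)·span, reactivity as the post-baseline sample nearest
the nominal peak time (default 25 min, the midpoint of the responder
window; ties to the earlier sample, linear interpolation optional) minus
baseline, and maximum increase clipped at 0. Model-based indicators
evaluate the fitted curve on the 1-min grid over [0, 80]: AUCg by
trapezoid (the closed-form gamma-CDF integral serves as test oracle),
AUCi relative to the curve's own value at t = 0, and reactivity at the
*structural* peak — the argmax of |A·f(t − dT)| — so that a declining
curve (A < 0) yields a negative reactivity proportional to A. This
choice is what makes ASM reactivity and ASM AUCi scale exactly linearly
with each other (both are linear in A_i), a property the evaluation
asserts as Spearman = 1. "True" indicators apply the same formulas to
the simulated red-noise trajectory without measurement noise, using the
trajectory's own argmax as the peak.

## The synthetic cohort generator

The generator emulates a TSST-like cohort observed continuously at 1-min
resolution from −20 to 80 min. Per individual, curve parameters are
drawn independently: log α ~ N(ln 3.0, 0.25), log β ~ N(ln 0.09, 0.20)
(population peak near (α−1)/β ≈ 22 min), log A ~ N(ln 240, 0.60) for the
80% responder fraction (peak height ≈ 6 nmol/L above baseline at the
median), A ~ N(0, 15²) for the 20% non-responders (flat and declining
profiles), and b0 ~ N(5.5, 1.5²) truncated at 1 nmol/L. Around the
structural curve, synthesis ("red") noise is a mean-zero
Ornstein–Uhlenbeck deviation D with dD = −θD dt + σ_red dW, θ = 0.05/min
and σ_red = 0.3, integrated by Euler–Maruyama on the 1-min grid with
D(−20) = 0, so the 20-min lead-in reaches the stationary SD
σ_red/√(2θ) ≈ 0.95 nmol/L before onset; centring the OU process on the
curve (rather than having it relax toward the curve) keeps the cohort
mean equal to the structural response and makes the noise-free limit
exact. Independent white measurement noise N(0, 0.5²) is added on top.
These values were chosen once as representative of afternoon salivary
cortisol studies and are all configurable.

What the generator does *not* emulate: anticipatory stress responses,
between-study protocol heterogeneity, assay floor/ceiling effects,
diurnal drift (b1 = 0 in the defaults), and individual peak-time jitter
beyond what α, β variation induces. Passing the evaluation on this
simulator therefore demonstrates schedule-robustness of the indicator
machinery under the stated noise model, not performance on any
particular empirical cohort.

Sampling schedules are downsampled views of the observed trajectory.
The shipped schedule sets honour the single-factor design — a duration
set sharing early timepoints with last samples at 40/60/80 min,
frequency sets spanning 0–80 with 3–9 samples, peak-timepoint sets
placing the peak sample at 15/25/35 min with late, early or no recovery
samples — plus a 12-schedule representative set and a 5-schedule
high-variability set including the very sparse {0, 30}. Jittered
designs draw per-individual timepoints from the stated mean (SD)
templates, rounded to the 1-min grid, clipped to [0, 80], redrawn on
ordering violations.

## Evaluation machinery

Rank-order accuracy is the Spearman correlation between "true" and
estimated indicators across individuals; stability is the mean pairwise
Spearman across a schedule set; combined-data evaluations allocate one
schedule per individual uniformly at random (10 replicates by default),
also computing the truncated-OBS variant (OBS_s: all series cut at the
latest timepoint common to every schedule) and the duration bias
(Spearman of indicator with allocated duration). Method comparisons use
paired t-tests on raw correlation vectors (no Fisher transform, which
would inflate effects at high r), exact sign-flip permutation tests over
the 2^10 = 1024 sign assignments of the replicate differences, and
Fisher-Z two-sample Z-tests per schedule (independent-samples
approximation; both correlations share the truth vector, so p-values are
approximate). Degenerate inputs are explicit: constant vectors make
Spearman undefined, zero-variance paired differences yield t = 0, p = 1
when all-zero and t = ±∞, p = 0 when constant-nonzero. No multiplicity
correction is applied; α = .05 two-sided throughout.

## Numerical choices and problem sizes

Peak search uses a 0.1-min grid over [0, 80] with ties to the earliest
time (robust when b1 ≠ 0, where no closed form exists); the gamma mode
is used only as a test oracle. The Gauss–Newton MAP solver damps per
individual (Levenberg-style λ adaptation), clips steps at 1.5 on the
transformed scale, and floors variances at 1e−12. EM convergence is
declared at a relative parameter change below `tol` (default 1e−5); the
MC noise floor means very tight tolerances may simply run out the
iteration budget, which is reported in `n_iter_`/`converged_` rather
than raised unless `require_convergence` is set.

The shipped experiments run at reduced scale — evaluation cohorts of
2,000 individuals with 10 combined-data replicates, training cohorts of
500, recovery studies at n = 200–500 — chosen so the full suite and the
acceptance script each complete in minutes while leaving the measured
patterns (duration bias of OBS AUCg, schedule-invariance of model-based
indicators, shrinkage ordering) far from their decision thresholds.

## Known limitations

- The gamma kernel cannot decouple recovery from reactivity; recovery-
  phase indicators are out of scope.
- The MM's log-normal amplitude cannot represent negative amplitudes, so
  declining profiles are fitted as near-zero responses with the drift
  and baseline absorbing what they can; the ASM represents decliners
  directly.
- Random-effect covariances are diagonal by default; the α–β trade-off
  therefore appears as inflated marginal variances rather than as a
  correlated pair.
- Covariate p-values come from a weighted regression on posterior means,
  an approximation to full Wald inference on the joint likelihood.
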