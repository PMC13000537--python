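# corticurve

Model-based salivary cortisol stress-response indicators that survive
heterogeneous saliva sampling schedules.

## The problem

Acute stress studies (TSST, gTSST, SECPT, MAST and their no-stress
controls) quantify HPA-axis activation with summary indicators computed
from a few timed cortisol samples: AUCg and AUCi (trapezoidal areas
under the cortisol–time curve with respect to ground and increase),
reactivity (cortisol at the expected peak minus baseline) and maximum
increase. These observation-based indicators depend on *when* saliva was
sampled — AUCg grows mechanically with sampling duration — so pooling
studies with different schedules, as individual-participant-data
meta-analyses must, biases them.

`corticurve` fits each participant a gamma-kernel response curve

    g(t) = A · f(t − dT; α, β) + b0 + b1 (t − dT),

where f is the gamma density (shape α, rate β), A scales the response
amplitude, b0 is the baseline, b1 an optional slow drift and dT an onset
shift, and computes all four indicators from the fitted curve on a
common 1-minute grid over [0, 80] min. Two estimators are provided as
scikit-learn-style models:

- **`AmplitudeScalingModel` (ASM)** — one population shape fitted by
  nonlinear least squares on stress-condition responders (rise ≥ 1.5
  nmol/L within 15–45 min; b0 fixed to the mean baseline), then only the
  amplitude re-estimated per individual by a closed-form least-squares
  scaling of baseline-normalized values.
- **`MultilevelGammaModel` (MM)** — a nonlinear mixed-effects model with
  log-normal random effects on α, β, A and normal effects on b0, b1, dT,
  covariate effects (gender, stress-test dummy codes) and a constant
  error model, estimated by a Monte-Carlo EM (importance-sampled
  posterior moments around a vectorized Laplace E-step) whose fixed
  point is exact marginal maximum likelihood. Individual estimates are
  empirical-Bayes, shrunk toward the population mean in proportion to
  their uncertainty.

A stochastic simulator (structural gamma curves + Ornstein–Uhlenbeck
"red" synthesis noise + white measurement noise, Euler–Maruyama on a
1-min grid from −20 to 80 min) generates cohorts whose full-resolution
trajectories provide "true" indicator values, and an evaluation suite
measures rank-order accuracy (Spearman against truth), cross-schedule
stability, combined-data accuracy loss and duration bias, with paired
t-tests, exact sign-flip permutation tests and Fisher-Z comparisons.

## Worked example

```python
from corticurve import (AmplitudeScalingModel, SimConfig, simulate_cohort,
                        downsample, indicators_model_based, indicators_obs)
from corticurve.evaluate import duration_robustness_experiment

cohort = simulate_cohort(SimConfig(n_individuals=300, seed=7))
train = [downsample(ind, tuple(float(t) for t in range(0, 81, 10))) for ind in cohort]
asm = AmplitudeScalingModel().fit(train)

series = downsample(cohort.individuals[0], (0.0, 15.0, 30.0, 45.0))
fit = asm.fit_individual(series)
obs = indicators_obs(series)
mod = indicators_model_based(fit.curve, method="ASM")
```

prints (via the calls shown in `scripts`/the snippet above):

```
population curve: {'alpha': 2.315, 'beta': 0.067, 'A_pop': 282.761, 'b0_pop': 5.497, 'b1': 0.0, 'dT': 0.0}
participant sim00000: A_i = 115.4
  OBS : AUCg=  455.8  AUCi=  80.3  reactivity= 1.82  max_inc= 3.34
  ASM : AUCg=  777.7  AUCi= 110.2  reactivity= 2.54  max_inc= 2.54
```

The participant was sampled only to 45 min, so the observation-based
AUCg (455.8 nmol/L·min) covers barely half the standard window, while
the model-based AUCg (777.7) extrapolates the fitted curve over the full
[0, 80] min — two participants sampled for different durations become
comparable. At cohort scale the effect is what matters:

```python
res = duration_robustness_experiment(n=800, n_replicates=5, seed=7)
print(res["summary"].query("indicator == 'AUCg'").round(3))
```

```
method  r_s_single  r_s_combined  accuracy_drop  r_s_duration
   OBS       0.987         0.805          0.183         0.555
   ASM       0.980         0.978          0.002         0.022
    MM       0.992         0.990          0.003         0.039
 OBS_s       0.987         0.953          0.035         0.019
```

When schedules of 40/60/80-min duration are mixed, observation-based
AUCg correlates strongly with allocated duration (r_s = 0.56) and its
rank accuracy against the true AUCg collapses from 0.987 to 0.805; both
model-based variants keep their single-schedule accuracy (drop ≤ 0.003)
and show no duration correlation. Truncating all series to the shortest
common duration (OBS_s) helps but discards data.

A CLI wraps the pipeline stages:

```bash
corticurve simulate --n 500 --seed 7 --out sim_out
corticurve fit-asm sim_out/cohort.csv --out population_curve.json
corticurve indicators sim_out/cohort.csv --method asm \
    --population-curve population_curve.json --out indicators.csv
corticurve evaluate --set duration --n 500 --replicates 10 --out eval_out
```

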