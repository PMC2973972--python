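# stopsig

Design, simulation and analysis of the **stop-signal anticipation task** — a
stop-signal paradigm with timed responses in which a visual cue signals the
probability (0–33 %) that the current response will have to be cancelled.
The package is aimed at researchers in response inhibition and cognitive
neuroimaging who want the full computational chain of such an experiment as
tested, reproducible code:

- **task design**: pseudorandomized trial sequences with exact per-level
  Go/Stop counts, alternating baseline/experimental blocks, rest blocks, and
  a regressor-correlation screen; BIDS-style `events.tsv` output;
- **staircase**: per-probability-level 1-up-1-down tracking of stop-signal
  onset (25-ms steps from 550 ms) that holds stop-success near 50 %;
- **race model**: a synthetic-behaviour generator — an independent horse
  race between an ex-Gaussian Go process (proactively slowed with cued
  stop-signal probability) and a Stop process of latency SSRT;
- **behaviour**: Tukey-fence outlier rule, RT/accuracy summaries,
  integration-method SSRT, ZRFT-normalized inhibition functions with a
  cumulative Weibull fit, linear-contrast and paired-t group statistics;
- **BOLD synthesis**: region × scan signals with planted condition
  amplitudes, parametric-modulator slopes, condition-dependent seed→sink
  coupling, ongoing neural fluctuation and AR(1) scanner noise;
- **GLM**: first-level event-related model with RT and probability
  modulators, 128-s discrete-cosine high-pass and bias-corrected AR(1)
  prewhitening; contrasts; second-level one-sample t and the
  probability × RT-bin repeated-measures ANOVA with Greenhouse–Geisser
  correction;
- **PPI**: seed eigenvariate, ridge hemodynamic deconvolution, ±1
  psychological vector at StopSuccess/StopFailure onsets, neural-level
  interaction, and prewhitened sink regression with task-condition nuisance.

Because all data come from the bundled generator, every stage is verified by
design-count identities and parameter recovery — the ground truth travels
with the dataset. See `docs/methods.md` for models, defaults and rationale.

## The models in brief

**Race model.** Stopping succeeds iff the Stop process beats the Go process:

    T_go = mu_go + beta * p_stop + N(0, sigma_go) + Exp(tau_go)
    StopSuccess  <=>  SSD + T_ssrt <= T_go,   T_ssrt ~ N(mu_ssrt, sigma_ssrt)

with SSD tracked by the staircase. The **integration method** inverts the
race: with response rate p over Stop trials,

    SSRT = GoRT_(ceil(p * n)) - mean(SSD),

and the **ZRFT** transform, `(mean GoRT − SSD − SSRT) / SD(GoRT)`,
standardizes inhibition functions for pooling across subjects.

**GLM.** `Y = X beta + e`, `e ~ AR(1)`; X holds HRF-convolved StopSuccess /
StopFailure / Go (p>0) impulses at response times, centred RT and p_stop
modulators, rest/outlier nuisance, cosine drift and intercept; baseline Go
trials form the implicit baseline.

**PPI.** For seed neural estimate x (deconvolved) and context c(t) = ±1 at
StopSuccess/StopFailure onsets, the sink is regressed on
`[h*x, h*c, h*(x.c), task nuisance]`; the interaction coefficient measures
the change in seed→sink coupling between the two stopping outcomes.

## Worked example

```python
from stopsig import (TaskConfig, build_trial_sequence, scheduled_duration,
                     SubjectParams, simulate_session, simulate_cohort,
                     rt_summary, ssrt_integration, inhibition_function)

cfg = TaskConfig()                     # canonical five-level parameterization
seq = build_trial_sequence(cfg, seed=7)
print(f"{len(seq)} trials, {scheduled_duration(cfg):.0f} s scheduled")

subject = SubjectParams()              # ~805 ms baseline RT, SSRT ~320 ms
session = simulate_session(seq, subject, seed=7)
print(rt_summary(session))
print(f"SSRT (integration method): {ssrt_integration(session):.1f} ms")

cohort = simulate_cohort(seq, 8, seed=7)
inh = inhibition_function(cohort, n_bins=12)
print(f"pooled inhibition function: Weibull R^2 = {inh.weibull.r2:.3f}")
```

prints

```
474 trials, 996 s scheduled
 level  p_stop  n_go  mean_rt  ci_low  ci_high  n_stop  stop_accuracy  n_outliers
     0       0   229    800.4   795.1    805.6       0            NaN           5
     1      17    30    794.8   778.6    811.0       6            0.2           0
     2      20    48    815.5   802.2    828.8      12            0.3           0
     3      25    54    821.8   810.3    833.3      18            0.5           0
     4      33    48    827.5   815.5    839.6      24            0.5           0
SSRT (integration method): 314.0 ms
pooled inhibition function: Weibull R^2 = 0.962
```

The 474 trials and 996-s duration are exact identities of the canonical
configuration (60 Stop trials, 234 baseline Go trials, probability labels
17/20/25/33 %). Mean Go RT rises with cued stop-signal probability —
proactive slowing — while the staircase holds Stop accuracy near 0.5; the
SSRT estimate of 314 ms sits close to this subject's generative stopping
latency of 320 ms, and the pooled inhibition function is well described by
the cumulative Weibull.

The fMRI side follows the same pattern (see `docs/methods.md` and the module
docstrings): `synthesize_bold` plants known effects, `FirstLevelGLM(...).fit()`
returns a results object with `.contrast(...)` and `.summary()`, and
`PPIModel(...).fit()` reports the interaction coefficient and its sign.

## Command line

A full synthetic study (24 subjects by default) runs as

```
stopsig run --config study.yaml --seed 42 --out runs/r1/
```

writing events, per-subject behaviour, behavioural summaries, BOLD matrices
with ground-truth sidecars, GLM and PPI first-level and group tables, and a
manifest with per-stage seeds. Individual stages are exposed as
`stopsig design | simulate | behavior | glm | ppi | fixtures`; the YAML
config mirrors `TaskConfig` plus population, region and scan parameters (see
`stopsig.pipeline.default_study_config`). Reruns with the same config and
seed reproduce every output byte for byte.

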