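# Methods

`stopsig` implements the full computational chain of a stop-signal
anticipation experiment — task construction, adaptive staircase, race-model
behaviour, SSRT estimation, event-related GLM with parametric modulators, and
psychophysiological interaction (PPI) analysis — together with a synthetic
data generator whose ground truth makes every analysis stage testable by
parameter recovery. This note records the models, the defaults and why they
were chosen, the numerical choices, and what the synthetic studies do and do
not establish about real data.

## The task and its design identities

On every trial a bar rises at constant speed toward a target line it reaches
in 800 ms; the subject stops the bar with a button press timed to the line
(timed, not speeded, responding). On Stop trials the bar halts on its own —
the stop-signal — and the response must be withheld. Stop-signal probability
is cued by the target-line colour; the default parameterization has five
levels (0, 17, 20, 25, 33 %) with per-level Stop counts (0, 6, 12, 18, 24),
234 baseline Go trials and Go counts on the p > 0 levels implied exactly by
`n_go = n_stop (1 − p)/p` (30, 48, 54, 48). Baseline blocks (0 % cues only)
alternate with experimental blocks, 12–15 trials each; two 24-s rest blocks
sit at one and two thirds of the run.

The published timing gives 800 ms to the target line, the line at 4/5 of the
bar's travel, and a 1000-ms intertrial interval, but no total trial duration.
We let the bar travel its full distance at constant speed — 1000 ms — giving
a 2000-ms onset-to-onset pitch. This uniquely reproduces the printed total
duration: 474 × 2 s + 2 × 24 s = 996 s (16 min 36 s). These identities
(counts, labels, duration) are exact and are asserted in the acceptance
suite.

Pseudorandomization is ours (the original ordering simulations are not
published): each experimental block opens with a Go trial, runs of Stop
trials are capped at two, and candidate orders are redrawn (deterministically
from the seed) until the design-time GLM regressors — Stop, Go p>0, and the
probability modulator, all HRF-convolved — have pairwise |r| below 0.4. The
canonical design passes at ≈ 0.24 on the first draw. When the baseline and
experimental trial totals admit equal block counts the blocks strictly
alternate; otherwise (only in scaled-down test configurations) the closest
feasible counts are interleaved evenly.

## Staircase

Stop-signal onset (SSD) starts at 550 ms — 250 ms before the target response
time — and moves 25 ms toward the target after each successful stop, 25 ms
away after each failure, independently per probability level. Bounds of
[50, 775] ms are ours (no published bounds); the upper bound keeps the
stop-signal strictly before the target response time, where a stop-signal is
meaningful. The tracker holds stop-success near 50 %: simulated medians per
level are 0.42–0.46 for levels with ≥ 12 Stop trials, and 0.50 ± 0.05 in the
long run (≥ 500 Stop trials). Levels with very few Stop trials (the 17 %
level has six) cannot clear the initial transient — the staircase needs
roughly four trials to walk from 550 ms to its equilibrium near 500 ms — so
convergence claims are made only where the trial count supports them.

## Race model (behaviour generator)

Per-trial outcomes come from an independent horse race. The Go finishing
time is ex-Gaussian — the standard RT distribution family —

    T_go = go_mu + slow_slope · p_stop + N(0, go_sigma) + Exp(go_tau),

with proactive slowing entering as a linear shift of the Go mean in the cued
stop-signal probability and no effect on stopping latency. On Stop trials,
stopping succeeds iff `SSD + T_ssrt ≤ T_go` with `T_ssrt ~ N(ssrt_mu,
ssrt_sigma)`; a trigger-failure probability (default 0) exists so estimator
bias under failed triggering can be studied. We use the independent rather
than the interactive race: the behavioural measures analysed downstream
(outcome frequencies, RTs, SSRT) depend only on race-consistent outcome
logic, and accumulator interaction is not identifiable from them. Go
omissions are not simulated.

Cohort defaults (population means, between-subject SDs in parentheses):
go_mu 775 (15), go_sigma 40 (5), go_tau 30 (5) ms — giving ≈ 805 ms baseline
responses; slow_slope 90 (20) ms per unit probability — ≈ 22 ms average
slowing over the p > 0 cues, matching the observed baseline-vs-anticipation
RT difference; ssrt_mu 320 (20), ssrt_sigma 30 (5) ms, in the range reported
for this task variant (stopping here is harder than in the classic speeded
paradigm). With these defaults the population-level RT profile is strictly
increasing across cue levels, but the 17 %→20 % step is only
90 × (0.2 − 1/6) = 3 ms — below the ≈ 2.4 ms sampling error of a 24-subject
cohort-mean difference — so strict sample-mean ordering holds in "most", not
"95 % of", cohorts. The suite therefore tests monotonicity where it is
decidable (a 200-subject pooled simulation) and the within-subject linear
contrast — the inferential claim — at the cohort scale, where it is
significant in every simulated cohort.

## Behavioural analysis

- **Outliers.** Per probability level, Go RTs outside the Tukey fences
  (1.5 × IQR beyond the 25th/75th percentiles, linear-interpolation
  quantiles) are flagged. Flagged trials are excluded from RT summaries and
  from the SSRT integration step, and enter the GLM as a no-interest
  regressor. With fewer than four RTs the rule is skipped with a warning.
- **SSRT (integration method).** Pooled over all p > 0 conditions:
  p_respond = StopFailure fraction over all Stop trials; SSRT is the
  ⌈p_respond · n⌉-th fastest retained Go RT (p > 0 levels) minus the mean
  SSD. The ceiling-index convention is the discrete fallback at small n;
  the estimator is undefined (raised) when p_respond is 0 or 1. Recovery:
  median |error| ≈ 4 ms at 600 Stop trials against the generative ssrt_mu.
- **Inhibition function.** Stop trials are binned by SSD; each bin is
  expressed as ZRFT = (mean Go RT − SSD − SSRT)/SD(Go RT) so curves pool
  across subjects. A cumulative Weibull
  `W(z) = γ − (γ − δ) exp(−((z − z0)/α)^β)` is fit by bounded, count-weighted
  least squares (γ ∈ [0.5, 1], δ ∈ [0, 0.5], α, β > 0; init γ=1, δ=0, α=1,
  β=2). `z0` anchors the curve at the smallest observed ZRFT because the
  power term is undefined for negative arguments; with fewer than three
  distinct points the fit is skipped. Pooled cohorts fit with R² ≈ 0.98.
- **Group statistics.** The linear-contrast trend test uses centred weights
  (−3, −1, 1, 3) on the four ordered p > 0 levels (the published weights are
  unstated; these are the standard choice), giving F(1, n−1) =
  n · mean(s)²/var(s) on per-subject scores. The paired t and one-sample t
  are classical; degenerate zero-variance inputs raise rather than return
  unstable numbers. 95 % CIs are t-based (the published CI method is
  unstated). Both tests are calibrated: null rejection 0.052 (linear
  contrast, slow_slope = 0 cohorts) and 0.042 (RM-ANOVA, below).

## BOLD synthesis

Regions are synthesized at ROI level — every in-scope statistic operates on
extracted series, and voxel-wise spatial inference is out of scope; a tiling
helper fabricates voxel matrices (region series + i.i.d. voxel noise) for
eigenvariate tests. Each region's neural signal is a train of impulses at
the response times — `onset + RT`, or `onset + target RT` for StopSuccess,
which has no overt response (an onset-locked switch exists) — scaled by
per-condition amplitudes plus slopes on the z-scored RT and probability
modulators (p > 0 Go trials only; baseline Go is the implicit baseline and
evokes nothing). Convolution with the canonical double-gamma HRF (peak
delay 6 s, undershoot delay 16 s, unit dispersions, undershoot ratio 1/6,
unit peak, 32-s support) runs on a microtime grid of TR/16; scans are read
at t = i · TR and AR(1) Gaussian measurement noise (unit marginal variance
scaled by `noise_sd`, lag-1 correlation `ar1_rho`, default 0.3) is added.
Because the GLM builds its regressors from the identical forward model,
noiseless synthesis is recovered to machine precision — the round-trip that
anchors all recovery tests.

Scan-count default: the full 622-volume acquisition at TR 1.6 s (995.2 s)
covers every trial of the 996-s task; the HRF tail of the last events is
truncated identically in synthesis and analysis, so estimates are unaffected.
When no scan count is given, synthesis auto-sizes to cover the last event
plus the full 32-s tail.

Two further fields make condition-dependent coupling generable and — more
importantly — identifiable:

- `coupling_seed` and `coupling_delta`: a sink region receives
  `(coupling_seed + context · coupling_delta) ×` the seed region's neural
  signal, with context +1 during StopSuccess trials, −1 during StopFailure
  trials (boxcars over the 2-s trial), 0 elsewhere.
- `neural_noise_sd` / `neural_noise_tau`: ongoing neural fluctuation — an
  exponentially correlated (OU) process at microtime, default time constant
  0.8 s — added to the region's neural signal before convolution. This is
  essential, not cosmetic: if the seed's neural signal were purely
  event-locked, the coupling change would be exactly collinear with the task
  condition regressors and no PPI could separate them. Real PPIs are driven
  by precisely this transmitted ongoing activity.

The default seed region's measurement noise is small (0.3 vs 1.0 for sinks)
because the seed series stands for the first eigenvariate of a voxel sphere,
where averaging suppresses voxel noise.

## First-level GLM

Design columns: StopSuccess, StopFailure, Go p>0 event regressors
(response-locked impulses, HRF-convolved), centred RT and probability
modulators on the retained Go p>0 events, rest-block boxcars (24 s), outlier
impulses, a discrete-cosine high-pass basis (periods > 128 s), optional
nuisance columns and an intercept. The modulators are not orthogonalized
against each other; their correlation (≈ 0.15 on canonical designs, screened
< 0.4) and variance-inflation factors are reported instead. Rank deficiency
raises an error naming the collinear columns (a session with constant Go RTs
is the canonical trigger: the centred RT modulator is identically zero).

Serial correlation: AR(1) prewhitening, estimated by a bias-corrected
fixed-point iteration. The naive two-pass scheme (estimate lag-1 from OLS
residuals, whiten once) under-whitens because residual autocorrelation is
biased toward zero by the design projection; measured CI coverage was 0.91
at nominal 0.95. We instead iterate (≤ 4 passes) until the whitened
residuals' lag-1 autocorrelation matches its *null* expectation
tr(LM)/tr(M), computed from the whitened design (L the symmetrized lag
operator, M the residual-forming projector). This recovers rho without bias
(0.294 at true 0.3) and gives 94–95 % CI coverage, while remaining a plain
linear solve per iteration — the simple estimator the restricted-maximum-
likelihood weighting it stands in for would give in expectation. rho is
pooled across regions for the filter (per-region estimates are retained as
diagnostics).

Contrasts are standard linear functions of the coefficients with t tests at
the whitened-model dof; the second level is a one-sample t over per-subject
estimates. The stop-signal-probability × RT-bin analysis uses per-subject
median splits within each probability level (the split rule is unstated in
the source analysis), F ratios from statsmodels' `AnovaRM`, and a
Greenhouse–Geisser epsilon computed from the within-subject covariance of
the effect contrasts, applied to the probability factor and the interaction
(a two-level factor needs none). GG under true sphericity is mildly
conservative; measured null rejection is 0.042 at n = 24.

## PPI

The analysis chain follows the standard seed-based PPI: (1) seed series =
first eigenvariate of the seed's voxel matrix (sign-aligned to the voxel
mean, unit variance; on region-level data the region series itself);
(2) hemodynamic deconvolution to a neural-level estimate; (3) psychological
vector = +1/−1 impulses at StopSuccess/StopFailure onsets on the microtime
grid; (4) interaction = elementwise product of neural estimate and
psychological vector; (5) all three reconvolved, sampled at TR, and entered
in a prewhitened regression on the sink series; (6) group-level one-sample t
over per-subject interaction coefficients. The psychological vector is not
mean-centred beyond its ±1 coding — the staircase balances the two outcome
counts — but a centring switch exists for unbalanced designs.

Deconvolution is generalized-ridge: minimize ‖Hx − y‖² + λ‖Dx‖² with H the
HRF convolve-and-sample operator at microtime TR/16 and D a first-difference
smoother; the smoothness penalty plays the role of the empirical-Bayes prior
on neural activity in the parametric-empirical-Bayes formulation it stands
in for (whose hyperparameters are not published). λ defaults to 1.0 and can
be set by generalized cross-validation (Hutchinson-probed hat-trace); on
noisy series GCV prefers heavy smoothing, which attenuates but does not
flip interaction estimates, so a fixed moderate λ is the default and the
`--lambda` override is exposed. The operator caches its sparse factorization
per (n_scans, TR, λ), so cohort-scale studies pay it once.

The sink regression includes the HRF-convolved task condition regressors as
nuisance covariates (the generalized-PPI safeguard). Without them the
sink's own evoked responses leak into the interaction term through its
correlation with the psychological regressor — in simulation this bias
exceeded and could flip a planted negative coupling. With them, recovery is
clean: planted coupling changes of ±0.8 are recovered with the correct sign
(and group significance) in 100 % of simulated 24-subject cohorts, the null
rejects at 0.05–0.06, and the forward analysis (true seed → sink) carries a
larger group effect than the reverse — PPIs are directional in practice even
though the regression itself is symmetric in form.

## Reproducibility and problem sizes

All randomness flows through numpy `SeedSequence`s: the pipeline derives
per-stage seeds as `SeedSequence(master, spawn_key=(stage_index,))` and
subject seeds by spawning, so any stage or subject can be regenerated in
isolation; identical config + seed reproduces every output byte for byte.

The acceptance studies (scripts/acceptance.py, mirrored by
tests/test_acceptance.py) use the canonical 474-trial design wherever the
claim concerns it (counts, duration, staircase, SSRT, race signatures) and a
scaled-down three-level, 72-trial task (~110 scans) for the fMRI-side
recovery and calibration studies, with replicate counts of 100–600 per
quantity — sizes at which a ±0.02 calibration band or a 90 % sign-recovery
threshold is statistically meaningful while a full run stays in the range of
a few minutes on one CPU.

## What the synthetic studies do and do not show

The generator plants the effects the analysis claims to measure, with
realistic trial counts, staircase dynamics, ex-Gaussian RTs, AR(1) scanner
noise and ongoing neural fluctuation. Passing tests therefore establish
that the estimators are correct and calibrated *under the generative model*:
the SSRT integration method recovers a known stopping latency, the GLM
recovers known amplitudes with honest uncertainty, the PPI recovers the sign
of a known coupling change at the stated cohort size. They do not establish
robustness to what the generator omits: head motion and physiological noise,
HRF shape variability across regions and subjects, nonlinear BOLD summation
at short event spacing, RT sequential effects (post-stop slowing, learning),
violations of race independence, or spatial structure of any kind. Voxel-
wise cluster inference, spatial preprocessing and anatomical localization
are out of scope by design.

Known limitations: the independent-race simplification (an interactive
accumulator would change none of the analysed statistics but is the richer
model); trigger failures default to 0 and are only exercised as a
directional bias study; the deconvolution λ is a stand-in for unpublished
empirical-Bayes hyperparameters; and the GG correction is mildly
conservative under exact sphericity.
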