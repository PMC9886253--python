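# Methods

## Generative observer model

The model describes one participant performing both tasks with a single
set of parameters — the contract that makes the cross-task analyses
meaningful. Per participant:

| parameter | meaning | distribution | units |
|---|---|---|---|
| `b` | speed bias under opposite-direction self-motion, as a fraction of the self-motion speed | `N(0.20, 0.30)` | – |
| `p` | fractional inflation of the speed-noise SD in that profile | `N(0.20, 0.30)` | – |
| `w` | Weber fraction of perceived speed | `N(0.10, 0.015)`, floored at 0.01 | – |

Population defaults (`PopulationParams`) are the study conditions; all are
configurable. The self-motion speed is 4 m/s, the distance Weber fraction
0.05, and the same-direction profile carries no effect by default
(`same_direction_weight` exposes it for sensitivity analyses).

Perceived ball speed on a trial is

```
v̂ ~ N( v + b·v_self·[opposite],  w·μ·(1 + p·[opposite]) ),   μ = v + b·v_self·[opposite]
```

truncated below at 0.05 m/s. Perceived occluded distance is
`d̂ ~ N(d, 0.05·d)` truncated positive, and the response time measured from
occlusion onset is `t̂ = d̂ / v̂`. The 2IFC choice is a comparison of one
draw of `v̂` for the ball against the comparison (cloud) speed.

**Noise base.** The Weber noise scales with the mean *percept* `μ`, not the
physical speed. With noise on the physical speed, a positive bias raises
the mean percept by exactly the factor by which the precision parameter
inflates the noise, so the coefficient of variation of `t̂` — and with it
any dispersion contrast that controls for the mean, as the preregistered
precision models do — becomes invariant to `p` at 4 m/s. That degenerate
coupling would make the precision hypotheses untestable by construction,
which contradicts the design's premise that they are testable; scaling
noise with the percept (the standard Weber-law reading) removes it.
`noise_base="physical"` is retained as an option.

**Comparison percept.** The ball cloud is the experimenter-controlled
comparison; it is modelled noise-free by default, so the fitted JND equals
the SD of the single-ball percept and the `(1+p)` inflation appears in the
JND ratio undiluted. `cloud_weber_scale` re-enables cloud noise as a
multiple of `w` (with equal cloud noise the predicted JND ratio shrinks
from 1.2 to ≈ 1.11).

**Truncations.** The 0.05 m/s percept floor and the positive-distance
floor are guards against the `1/v̂` singularity; both are configurable
constants. They give the timing-error distribution a heavy right tail for
strongly negative-bias participants — intended behaviour, handled by the
preregistered timeout exclusion.

## Design and kinematics

The prediction design crosses 3 ball speeds × 3 motion profiles × 3
occlusion durations, plus six static-only occlusions (0.1–0.4, 0.8, 0.9 s)
for the variability-versus-occlusion map: (27 + 18) cells × repetitions
(225 trials at 5 repetitions, 585 at 13). Directions alternate within each
cell; trial order is a seeded uniform shuffle. The speed task enumerates
18 staircase conditions.

The self-motion profile ramps to 4 m/s over 50 ms, holds for 400 ms and
ramps down over 50 ms. The ramp is a Gaussian CDF with
`σ = ramp_duration / 4`, truncated to the ramp window and rescaled — a
smooth, symmetric sigmoid whose displacement (`peak · ramp/2` per ramp,
1.8 m total) is independent of `σ`; `σ` is exposed in the kinematics
object. Retinal speeds and angular extents come from
`θ(t) = atan((x_ball − x_obs)/8)` with gaze locked straight ahead in the
translating head frame, integrated at ≤ 1 ms steps; the observer is
parked at the final 1.8 m displacement during the occlusion. The full
design stays within a 60° field (max ≈ 53.8°). The published table of mean
absolute retinal speeds is not used as a reference: its values are not
internally consistent with this geometry (e.g. a near-zero entry for a
static observer viewing a 4 m/s ball at 8 m, where the geometry gives
≈ 28.5°/s), so the package reports its own computation.

## Staircase

The comparison speed follows PEST magnitude rules: halve the step on a
reversal; the second same-direction step repeats the first; the fourth and
later double; the third doubles unless the step immediately preceding the
most recent reversal was itself a doubling. Two modifications from the
protocol: staircases start ±30% around the reference with the step pinned
at 1.2 m/s (twice the 0.6 m/s initial step) for the first ten trials, and
levels are clamped to `[reference/3, 3·reference]` (clamping is not a
reversal). A staircase ends after 37 trials, or once ≥ 30 trials are done
and the next step is below 0.03 m/s — so every staircase takes 30–37
trials and a session 540–666. Design choices: stepping happens after every
trial (the Wald sequential criterion of classic PEST is off by default,
available via `use_wald`); when the boost phase ends the bookkeeping
restarts at the 0.6 m/s initial step; the post-boost step is capped at
1.2 m/s.

## Psychometric fitting

P(comparison judged faster) is a 2-parameter cumulative Gaussian
`Φ((x − μ)/σ)` (no lapse or guess parameters), fitted per participant ×
speed × profile on the pooled trials of the condition's two staircases by
direct likelihood maximisation: bounded L-BFGS-B with the analytic
gradient, from a probit-regression start plus quantile-spread restarts
(5 in the analysis path, 2 in the power loop — they agree on these data).
`σ` is bounded in `[10⁻³, 3·reference]`. μ is the PSE; σ is the JND, i.e.
the 84.1%-point minus the PSE. All-identical responses or a single level
leave the parameters unidentified; such fits carry `converged=False` and
are excluded downstream.

## Exclusion rules

Applied before inference, mutually independent and idempotent:
(a) prediction trials answered later than 3× the occlusion duration
(timing is measured from ball disappearance, matching the dependent
variable); (b) participants with > 20% of comparison speeds at a staircase
limit (within 10⁻⁹ after clamping) leave the speed task; (c) precision
analyses drop condition cells with SD ≤ 0.01 (seconds or m/s) before
taking logs; (d) trials with ≥ half of the recorded head-rotation bins
outside ±2.5° are dropped in both tasks when head recordings exist (the
simulator generates compliant `N(0°, 1°)` bins on request, with an
injectable non-compliant offset for testing the filter).

## Statistical pipeline

Treatment coding with "static" as reference throughout. All LRT model
pairs are refitted by ML (not REML) since their fixed effects differ. The
mixed-model backend supports the occlusion-duration intercepts as a
variance component within participants rather than fully crossed random
effects; the fallback ladder is (1) that structure, (2) occlusion as a
fixed covariate, (3) random intercept only, and every fit records the rung
used. The random ball-speed slope is fitted on the centred covariate — an
equivalent reparametrisation that markedly improves optimiser behaviour.
LRT pairs are fitted jointly on the same rung; because these dispersion
models often sit on a variance boundary where convergence flags are
unreliable (in any backend), a member flagged non-converged — or a test
model below its nested null, which is impossible in exact arithmetic — is
refitted with several optimisers and the best likelihood kept.

Coefficient significance runs on two routes: participant-cluster
percentile bootstrap CIs (default 1000 resamples) for reporting, and the
fast Wald z approximation inside the Monte-Carlo power loop. Precision
models (the H1b/H2b/H3b comparisons) are decided by the LRT only; their
coefficients are never reported as effect estimates because the dispersion
response is correlated with its mean covariate. H2b is decided on the
static + opposite subset (the static + same variant is available the same
way). The H3 link models are ordinary regressions on one row per
participant, built from (opposite − static) differences over the shared
occlusion durations.

## Calibration

Per participant and task, two bounded Brent minimisations of the
root-median-squared error between observed and simulated condition
differences: first the bias parameter with the precision parameter pinned
at zero (per-cell mean timing-error differences, or per-speed PSE
differences), then the precision parameter with the bias fixed (SD or JND
differences) — the order is enforced. Each objective evaluation
re-simulates a batch of sessions (default 200) with common random numbers
frozen per fit, making the objective deterministic and Brent-friendly;
nuisance parameters sit at their population means. Search bounds are
[−1, 2] with `xatol = 10⁻³`; estimates within 2·xatol of a bound are
flagged. For the speed task the simulated PSEs/JNDs come from a
constant-stimuli probe of the same 2IFC choice model, fitted with the same
psychometric code as the observed data — re-running the adaptive staircase
inside every Brent iterate would cost ~10³ more for no extra
identifiability. The dispersion objective compares SD(self-motion cell) −
SD(static cell) by default; `sd_objective="sd_of_differences"` instead
uses the SD of self-motion timing errors centred on the static cell mean
(an unpaired design has no trial-level pairing, so a literal SD of paired
differences does not exist). Under shared participant parameters the
across-participant regression of prediction-task on speed-task bias
estimates has slope ≈ 1 with R² ≈ 0.97 at 40 participants.

## Power engine

`simulate_experiment` draws a cohort, runs both task simulators and
returns raw trial logs; `power_cell` repeats simulate → exclude → fit →
test and reports per-hypothesis rejection rates. Per-simulation seeds are
spawned from the master seed, so results are independent of the worker
count (`joblib`). The loop uses the reduced-cost route: Wald z tests,
the fixed-occlusion mixed-model rung, and 2-start psychometric fits. The
design grid is 20/30/40 participants × 5/9/13 repetitions × staircase
bands (20–27, 30–37, 40–47 trials, i.e. ≈ 50/70/90 pooled trials per
condition). Full runs use 250 simulations per cell (hours on one CPU);
the test suite and quick CLI mode use 50 and 20 respectively, sized so a
rate is still meaningfully localised by its binomial CI. Type-I
calibration forces the means *and* between-participant SDs of both effect
fractions to zero and reports rejection rates with the exact binomial 99%
band.

At the protocol's chosen design (40 participants, 13 repetitions, 30–37
staircase trials) five of the six tests exceed 0.85 power under the
default generative model; the speed-task precision test (H2b) reaches only
≈ 0.5–0.6 and is the grid's bottleneck. The shortfall is structural, not a
tuning artefact: the H2b model controls log(JND) for the PSE, and with
staircase-estimated psychometric parameters the PSE covariate absorbs part
of the true precision effect — PSE and JND estimation errors from the same
fit are correlated, and bias heterogeneity couples the two through the
percept-scaled noise — leaving a mean profile coefficient of ≈ 0.11
against a standard error of ≈ 0.055. Even with error-free JNDs the test
tops out near 0.8 under the 0.30 between-participant SD. JND estimation
itself is efficient (the fitted SD matches the Cramér–Rao bound on the
realised staircase levels), so more power requires more trials per
condition, lower effect heterogeneity, or a different precision test.

## What the synthetic data do and do not emulate

The generator reproduces the design arithmetic, staircase dynamics,
Weber-law noise structure, between-participant heterogeneity and the
shared-parameter linkage. It does not model reaction-time processes
(responses are percept-determined), lapses or guessing, eye movements or
gaze-tracking effects, depth misperception (assumed to cancel between
distance and speed), perceptual learning, or any same-direction effects by
default. Passing tests therefore validate the pipeline's behaviour under
the stated perceptual model — not the empirical truth of that model, nor
analysis behaviour under real-data pathologies such as attention lapses
beyond the simple timeout mechanism.

## Numerical choices

Velocity integrals use trapezoids at 0.1 ms (1 ms in the acceptance
script); psychometric likelihoods clip probabilities at 10⁻¹⁰; bootstrap
replicates that fail to fit are dropped from the percentile computation;
degenerate LRTs (zero extra parameters, rank-deficient OLS pairs) return
p = 1 for a zero statistic. Reproducibility is bit-exact given a master
seed: cohorts, sessions, bootstrap and calibration all derive their
streams from it.
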