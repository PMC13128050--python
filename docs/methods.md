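# Methods

This note documents the models, parameter choices and numerical decisions
behind `rampgait`, in the order data flows through the package.

## Scope and data model

The unit of analysis is a *trial*: one overground pass along a level path
(7 m) or a 7° ramp (3.25 m, ascent or descent), recorded at a fixed
sampling rate (default 60 Hz) as sagittal joint angles (hip, knee, ankle;
flexion/dorsiflexion positive) for both limbs plus anterior–posterior and
vertical positions of heel, toe and pelvis landmarks per side. Trials are
grouped into participants (each walking several trials per condition) and
participants into two groups (young / older adults). Frontal- and
transverse-plane motion, kinetics, and the capture system itself are out
of scope: the pipeline starts from exported time series.

## Smoothing

Two smoothers are provided.

* `lowpass`: the gait-lab standard zero-phase dual-pass 2nd-order
  Butterworth with Winter's cutoff correction, giving a 4th-order
  zero-phase response that is −3 dB at the nominal cutoff (default 6 Hz).
* `gcv_smooth`: penalized least squares with a second-difference penalty
  (the discrete analogue of a cubic smoothing spline), diagonalized by the
  DCT for uniformly sampled series, with the smoothing parameter chosen by
  generalized cross-validation over a log grid plus parabolic refinement.
  A cross-check test pins it against `scipy.interpolate.make_smoothing_spline`
  (the general-grid GCV spline) on noisy fixtures.

The pipeline default is the GCV smoother, and this is a deliberate
methodological choice: gait waveforms at a ~0.85 Hz stride rate carry
meaningful harmonic content at 2.5–4.5 Hz, which sits on the shoulder of a
fixed 6 Hz 4th-order zero-phase filter. Measured on realistic knee
waveforms, the fixed filter clips flexion peaks by 0.15–0.30°, a bias of
the same order as the effects of interest; the GCV smoother is
data-adaptive — essentially the identity on noise-free series, and close
to the white-noise floor on noisy ones — so peak amplitudes survive. The
Butterworth remains available (`RunConfig(filter_method="butterworth")`)
for sensitivity analyses against legacy processing.

## Event detection

Walking direction is the first principal axis of the pelvis trajectory,
signed so the projection increases over the trial; a net displacement
below 0.5 m is rejected as a stationary trial. Per side, initial contacts
are local maxima of heel−pelvis and toe-offs local minima of toe−pelvis
along that axis. Acceptance rules: prominence ≥ 20 % of the signal's
interquartile range and ≥ 0.3 s between same-kind events (admitting
cadences to 200 steps/min); plateau ties resolve to the first frame.
Detected per-side sequences must alternate IC/TO with ipsilateral ICs
≥ 0.4 s apart, or detection fails loudly with the offending frames. The
projection makes detection exactly invariant to rigid rotation and
translation of the capture frame (a property test).

Foot-strike classification compares heel and toe height along the
walkway-normal axis (perpendicular to the walking direction) at the IC
frame: heel at or below toe ⇒ heel strike. The threshold (0 cm) is
configurable; the criterion is a kinematic proxy chosen for determinism.

Instead of manual event correction, a QC rule flags cycles whose duration
deviates more than 3 scale units from the trial median, using an
SD-consistent MAD as the scale. A plain SD cannot work here: with the
2–6 cycles a trial yields, max |deviation|/SD is bounded by √(n−1) < 3, so
a plain-SD rule can never fire; the MAD realizes the intent. Flagged
cycles are excluded from averaging and reported in the QC output.

## Trimming, cycles, representative waveforms

Steps are ICs of either foot in temporal order, 1-indexed. Level trials
analyze steps 3..N−3 (gait initiation and termination excluded), ramp
trials steps 2..N−1; a cycle enters analysis only if both of its bounding
ipsilateral ICs are kept. Cycles must contain exactly one ipsilateral
toe-off; others are discarded with a logged reason.

Each cycle is resampled to the canonical 101-point grid by cubic
interpolation on its own time base, endpoints preserved exactly;
`to_percent` is the toe-off location in % cycle. Averaging is
hierarchical: cycle mean per trial and side → left/right mean (falling
back to the present side with a warning when one side yields no cycles,
which short ramps regularly cause) → mean across trials. The SD band is
computed across trial-level waveforms, matching the averaging hierarchy;
with a single trial it is reported as zero.

## Representative values and spatiotemporal parameters

The cycle is partitioned at mid-stance and toe-off. Mid-stance is not
observable from events alone, so it defaults to the temporal midpoint of
stance (`to_percent / 2`); a fixed percentage is configurable. The twelve
values per condition are window extrema on the averaged waveform: RoM
(max − min over the full cycle), hip/knee stance and swing flexion maxima,
stance minima reported *signed* (negative = hyperextension; note that
summary tables in the field often print hip extension as a positive
magnitude — the bundled calibration targets handle the sign conversion),
ankle dorsiflexion maximum in ST2, peak plantarflexion as a positive
magnitude within toe-off ± 10 % cycle (the push-off peak straddles
toe-off; the half-width is configurable), and the signed ankle angle at
0 % cycle.

Spatiotemporal parameters use only the kept window: cadence =
60·(n_IC−1)/Δt; step length = mean heel-to-heel separation along the
walking direction at bilateral ICs (along-slope on ramps); velocity =
pelvis displacement along the walking direction divided by the window
duration. Heel-based step length and pelvis-based velocity are
assumptions made explicit here; both are the simplest observable
definitions consistent with the landmark set.

## Statistics

**Spatiotemporal tier.** Independent two-sample t tests per parameter ×
condition; the pooled-variance (Student) flavor is the default because it
is the one consistent with pooled-SD Cohen's d (Welch is available).
BH-FDR is applied within each parameter across its three conditions by
default; a pooled family is a config switch, since the appropriate family
is a reporting choice. Magnitude bands: negligible |d| < 0.2, small
< 0.5, medium < 0.8, large ≥ 0.8 (boundary inclusive on the large side).
Shapiro–Wilk normality checks are reported but never gate the pipeline.

**Joint-angle tier.** One model per parameter (12 models; with all three
conditions present each yields 3 per-condition contrasts, i.e. 36
comparisons):

    value_ij = β₀ + β_v·velocity_ij + group_i × condition_j + b_i + ε_ij,
    b_i ~ N(0, σ²_participant),  ε_ij ~ N(0, σ²_resid),  REML

with one observation per participant × condition and sum-to-zero contrasts
so Wald F tests of coefficient blocks are type-III tests. The REML
optimum comes from `statsmodels` MixedLM; fixed effects, their covariance,
F statistics, EMMs and contrasts are then computed from closed-form
random-intercept algebra at those variance estimates. Satterthwaite
denominator df follow the standard construction: ν = 2g²/(∇gᵀA∇g), where
g(θ) is the contrast variance as a function of (σ²_participant, σ²_resid),
differentiated numerically (relative central differences), and A is the
inverse observed REML information (numerical Hessian of the closed-form
REML log-likelihood). Multi-df terms combine per-eigencontrast dfs; a
residual-df fallback (n − rank X) is used when the information matrix is
not usable (e.g. boundary fits) and is what degenerate fits report. The
whole stack is validated to 3–4 significant figures (F, df, p, contrast
SEs) against lme4/lmerTest/emmeans on a frozen fixture
(`tests/data/`, regenerable via `tests/data/lmm_oracle.R`).

EMMs are evaluated at the grand mean of the velocity covariate over all
observations (the standard covariate-adjustment convention; a
per-condition reference would answer a different question). Simple
effects (young − old within condition) are evaluated only when the
unadjusted interaction p < 0.05 — the gate mirrors the common reporting
rule, and FDR is applied afterwards to the *evaluated* simple-effect
p-values pooled across parameters and conditions. Effect size is the EMM
difference divided by the model residual SD.

**Degenerate fits.** Noise-free synthetic cohorts produce responses that
are exact linear functions of the design; REML is then ill-posed. Such
fits are detected (OLS residual variance at machine zero) and returned on
an exact-OLS path with zero variance components, flagged `degenerate`:
estimates and EMMs are exact, while SEs/p-values/d are reported as
0/NaN/NaN rather than fabricated.

**BH adjustment.** Adjusted p-values follow the textbook step-up
(implemented via statsmodels, property-tested against a hand-coded
oracle). Note that BH-adjusted p-values are *not* idempotent as a vector
map — re-adjusting [0.5, 1.0] gives [1.0, 1.0] — the invariant that holds,
and is tested, is decision equivalence: thresholding adjusted p-values at
α reproduces the step-up procedure's rejection set at every α.

## Synthetic cohort generator

The generator exists so every stage can be tested against exact ground
truth; its defaults encode the study design it emulates (20 + 20
participants, three conditions, five trials each, 60 Hz).

*Waveforms.* Each joint's cycle is a 1-periodic monotone-cubic (PCHIP)
curve through keypoints laid out from typical adult gait morphology
(early-stance knee flexion bump at ~25 % of stance, stance extension
minimum, large swing peak; hip flexed at contact, extending to ~87 % of
stance, re-flexing in swing; ankle dip–dorsiflexion–push-off). Monotone
interpolation cannot overshoot, so every local extremum is a keypoint and
requested representative values are met exactly; the builder self-checks
by extracting features from its own noiseless cycle (tolerance 0.1°) and
rejects infeasible target sets with a diagnostic. Keypoint phases snap to
the 1 %-cycle grid so sampled extrema are exact. Published per-condition
group values are velocity-adjusted model means, which need not be mutually
consistent as one waveform (e.g. a printed knee RoM smaller than its
printed swing peak minus stance minimum); in lenient mode a contradictory
RoM request is dropped and recorded on the template, and the bundled
calibration uses exactly that rule — named extrema exact, RoM emergent.

*Trajectories.* Stance occupies 0.60 of the stride (a typical value; the
emulated protocol does not report one; configurable), feet alternate
stance (stationary) and swing (linear advance with a sinusoidal clearance
bump; the toe lands 2 cm proud and settles, producing heel strikes), and
the pelvis follows a trapezoidal velocity profile: linear ramp-up from
standing to steady speed at the first IC, constant speed through the last
IC, ~1 s ramp-down. This construction makes the heel–pelvis maxima and
toe–pelvis minima fall *exactly* on the ground-truth IC/TO frames, so
noise-free detection recovers every event exactly (a test), and the first
and last events have enough prominence to clear the detector's floor.
Stride timing is quantized to whole frames; cadence is reported as
realized and step length is derived from the realized cadence so the drawn
velocity is reproduced exactly. Ramp trials run on a uniform 7° slope
with vertical = tan(7°) × horizontal progress; the usable path extends 1 m
past the nominal walkway (start/stop points and the ramp landing lie
outside the measured span — without this, a tall-stepping participant
cannot fit the minimum step count the trimming rules need).

*Cohort structure.* Three noise tiers mirror the repeated-measures
analysis: per-participant feature offsets (random intercept, default SD
3°), participant × condition residuals (default SD 2°), and frame-level
measurement noise (default SD 1° on angles, with proportional landmark
jitter of 1.6 cm/°, the displacement a 1° error subtends over ~0.9 m of
limb). Velocity and cadence combine a participant propensity with
condition jitter (weights 0.8/0.6) so fast walkers are fast everywhere.
All draws come from one seeded generator in a documented order; identical
specs are bit-identical. Each group cell's draws are standardized to
exact sample moments (mean and SD), because published group tables report
the *sample* statistics of the studied participants — a cohort calibrated
to them should realize those statistics, not merely target them in
expectation (at n = 20 and SD 0.10 m/s, an unstandardized sample mean
misses the table value by more than 2 % about a third of the time).
Extreme-tail draws are clamped to feasibility (plantarflexion magnitude
above the IC angle, step lengths that fit the walkway with enough steps
for the trimming rule); this truncates well under 1 % of the distribution.

*What the generator does not emulate* — and hence what passing round-trips
do and do not show: no biomechanically validated forward dynamics, no
marker or video simulation, no within-trial stride-to-stride variability
(cycle durations are exactly periodic within a trial), no correlated or
autoregressive measurement noise, no missing data, and no velocity–angle
coupling within groups (angles are conditionally independent of the drawn
velocity, so the LMM's velocity adjustment is exercised for orthogonality,
not for confounding removal). Round-trip agreement therefore validates
the pipeline's bookkeeping, event logic, resampling accuracy and
statistical machinery on data with the study's structure — it does not
validate the biomechanics of real ramp walking.

## Problem sizes used by the tests and acceptance script

Full-size cohorts (20 + 20 participants × 3 conditions × 5 trials, ≈ 600
trials) run end-to-end in ~15 s, so the calibrated round-trips use the
study-sized design unreduced. Mixed-model calibration uses 500 null
simulations (type-I error of the type-III group test within [0.03, 0.07]
at α = 0.05) and 400 effect simulations (contrast bias < 0.1°, 95 % CI
coverage within [92, 98] %), drawn directly from the random-intercept
model at the study's variance tiers. Oracle-equivalence suites use
100–1000 randomized fixtures per operation. The whole test suite runs in
a few minutes on one CPU.

## Known limitations

* The GCV smoother assumes uniform sampling and white noise; heavy-tailed
  or correlated noise would need the spline variant on an explicit grid.
* Satterthwaite dfs rely on numerical differentiation; at variance
  boundaries (σ²_participant → 0) the residual-df fallback is used and
  labelled.
* Mid-stance as half of stance is a convention, not a measurement; ST1/ST2
  splits shift accordingly if a different rule is configured.
* The t-test tier's FDR family (per parameter vs pooled) is a reporting
  choice; both are implemented, neither is canonical.
* Single-condition runs skip the mixed-model tier (a within-participant
  condition factor needs ≥ 2 conditions).
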