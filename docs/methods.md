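# Methods

`smx` implements the measurement and analysis chain of a sensorimotor study
design comparing blind/visually-impaired (BVI) and sighted children on
balance, gait, physical activity, and path-integration navigation, together
with a synthetic-cohort generator that provides ground truth for every
stage. This note documents the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic validation does and
does not establish.

## Posturography: 95% prediction ellipse area (PEA)

A centre-of-pressure (CoP) trace is a 2-D time series (medial-lateral,
anterior-posterior, cm) sampled at 180 Hz for 30 s per trial. The sway
summary is the area of the 95% prediction ellipse: with sample mean `m` and
covariance `S` (n−1 denominator), the ellipse is
`(z − m)' S⁻¹ (z − m) ≤ k` with the F-based small-sample factor

    k = 2 (n+1)(n−1) / (n (n−2)) · F(0.95; 2, n−2),

and area `π·k·√det S`. At n = 5400 this factor is within 0.1% of the
chi-square limit `χ²(0.95, 2) ≈ 5.991`, which is the closed form the tests
check against. Serial correlation of CoP samples is ignored in the scale
factor — the standard PEA convention: the ellipse then describes the
dispersion of the sampled sway path, not an i.i.d.-calibrated forecast.
CoP data enter unfiltered; a zero-phase Butterworth low-pass is available
as an option (`lowpass_hz`) for sensitivity analyses only. The trial-level
dependent variable is the arithmetic mean area over the (typically three)
trials of a stance/vision condition.

Degenerate traces (fewer than 3 samples, zero or collinear variance) are
rejected rather than returned as zero-area ellipses.

## Gait: stride segmentation, variability, local dynamic stability

Input is a 3-axis foot angular-velocity trace (rad/s, 100 Hz) from a
6-minute hallway walk, annotated with 25 m bout boundaries and a
non-stationarity mask.

**Exclusions.** The first and last full bout, the first and last 2.5 m of
each remaining bout, and masked samples are removed before analysis.
Within a bout, distance is mapped linearly to time (no dead reckoning is
performed, so 2.5 m of 25 m = 10% of the bout's samples at each end).

**Stride events** are prominent sagittal-channel peaks
(`scipy.signal.find_peaks`, minimum separation 0.4 s, prominence ≥ 2
rad/s by default). Detection runs per bout and stride times are formed only
between consecutive events of the same bout. The detector is
contract-equivalent, not a reproduction of any proprietary sensor
algorithm: its requirement, enforced by tests, is exact event recovery
(±1 sample) on synthetic gait with known event times. Stride-time
variability is the n−1 standard deviation of the stride times.

**Local dynamic stability.** The first 63 complete strides are each
linearly resampled to 100 samples (6300 samples total), putting all strides
on a common phase axis. The three channels are delay-embedded with delay
τ = 11 samples and 5 delayed copies per channel (total dimension 15) by
default; τ and the per-channel dimension can instead be selected
automatically from the first minimum of the average mutual information
(AMI) and the false-nearest-neighbour (FNN) criterion. Interpreting a
total dimension of 15 as 3 channels × 5 copies is the standard multichannel
embedding reading. The largest Lyapunov exponent is computed with the
Rosenstein nearest-neighbour method: each state is paired with its nearest
Euclidean neighbour outside a Theiler window of 100 samples (one stride),
the divergence curve is the mean log distance of surviving pairs after k
steps, and the exponent is the least-squares slope over steps 0–50
(0–0.5 stride), reported in nats per stride. Higher values mean faster
local divergence, i.e. lower stability.

Numerical details:

* Nearest-neighbour search is brute force in 512-row blocks (n ≈ 6·10³ is
  desk scale); pairs that run off the series drop out of the divergence
  mean rather than truncating the curve.
* Zero distances (exact recurrences) are floored at 10⁻¹² of the mean state
  norm, so an exactly periodic orbit yields a flat curve and a zero
  exponent instead of −∞.
* The AMI estimator uses 16 equiprobable (rank-based) bins. The "first
  minimum" uses a ±3-lag comparison window: on the flat valley of a noisy
  AMI curve the textbook one-lag rule fires on estimator jitter, and on
  noiseless strictly periodic signals the binned estimator oscillates with
  bin-edge aliasing, so a windowed minimum is the robust reading of the
  same convention.
* FNN uses the Kennel thresholds rtol = 15, attractor-size factor 2, and a
  1% false-neighbour cutoff; on noise it correctly never converges and
  returns `max_dim` with a warning.
* The fit window must sit in the scaling region of the divergence curve.
  For the stride-normalised gait series this is the short-term 0–0.5 stride
  window conventional in the gait-stability literature. For the Lorenz
  benchmark (dt = 0.01) the first ~60 steps are a neighbour-alignment
  transient, so validation fits steps 100–300; for the logistic map the
  curve saturates after ~8 steps, so validation fits steps 0–5. These are
  properties of the systems, not tuning knobs of the estimator.

Validation anchors: the r = 4 logistic map (exact exponent ln 2), a
noise-free periodic signal (exponent 0), and the Lorenz system, where the
embedding estimate is compared against an independent tangent-space
(Benettin) integration of the exact variational equations (≈ 0.91
nats/time-unit at σ = 10, ρ = 28, β = 8/3).

## Navigation: triangle completion scoring

A trial is the guided path A→B→C plus the participant's stopping point P.
Both errors are defined at the turning point C:

* signed angle error = (signed turn from heading B→C to C→P) − (signed
  turn from B→C to C→A), wrapped to (−180°, 180°];
* signed distance error = |P−C| − |A−C| (negative = underestimated path).

The absolute values are the dependent variables; the Euclidean endpoint
miss |P−A| is kept as an auxiliary measure. Scores are invariant under
rigid motions of all four points, and mirrored (clockwise) presentations
give identical absolute errors with flipped signs. The two reference
triangles are an equilateral triangle with 300 cm sides and a 30-60-90
right triangle with hypotenuse 300 cm (legs 150 and 150√3 cm) used as the
homing segment; only the admissible 150–300 cm segment range and the angle
set are constrained by the design, so the absolute sizes are fixed here at
the top of that range and are configurable.

## Statistics

The analysis layer mirrors a matched two-group design with repeated
conditions:

* **Mixed 2×2 ANOVA** (between: group; within: condition) via the classical
  univariate decomposition: the between test is a one-way ANOVA on subject
  means (df 1, N−2), the within and interaction tests are contrasts on
  per-subject difference scores with a pooled error term (df 1, N−2). With
  unequal group sizes the condition main effect is the unweighted mean of
  group difference-means — the Type III convention. Degrees of freedom
  follow whatever rows are present, so missing data change df bookkeeping
  rather than being imputed.
* **Levene's test** (classic mean-centred form, via scipy) gates the
  heteroscedasticity correction: when Levene p < 0.05 the affected tests
  are recomputed as Wald tests with an HC3 White–Huber sandwich covariance
  (statsmodels OLS on the cell-means design). HC3 is chosen for its
  small-sample behaviour at n = 14 per group.
* **Effect sizes**: Cohen's d with n−1 pooled sd and a 95% CI from
  noncentral-t inversion. For within-subject contrasts, d standardises the
  mean difference by the sd pooled across the two condition cells (the
  difference-score sd is used only for the interaction), documented because
  several conventions exist.
* **Marginal-mean contrasts** carry Tukey (studentized-range) adjustment;
  for 2-level factors the adjustment is an identity, verified against
  statsmodels' `pairwise_tukeyhsd` for the 3-level case.
* **Correlations**: per-group two-sided Pearson r with t-based p (df n−2)
  and Fisher-z 95% CI, computed on eyes-closed data, with sway averaged
  over stances.

`reproduce_analysis` chains the pieces: per outcome, the BVI-vs-sighted
comparison on eyes-closed data (mixed 2×2 where a within factor exists,
one-way otherwise, Levene-gated HC correction), the eyes-open vs.
eyes-closed paired contrast within the sighted group (averaging over stance
where both stances exist, df n−1), and the per-group correlation matrix of
exercise/basic-activity minutes with every outcome. Missing outcomes
produce warnings, never errors.

## Synthetic cohorts

The generator exists so every stage above can be validated against known
generating values; it emulates the study's data streams, not their
biomechanics.

**Latent structure.** Each participant has an exercise score
`E ~ lognormal(μ_group, σ = 0.4)` (medians 150 min/week BVI, 270 sighted —
a sedentary shift of plausible size). The group-standardised latent
`z = (log E − μ_group)/σ` loads on every outcome
(`value = base + group_offset·[BVI] + loading·z + noise`), with negative
loadings for sway area, stride-time variability, LLE and navigation errors
and a positive loading for stance time. Basic everyday activity is
generated independently of the latent factor. A single-factor structure is
the simplest model that produces a one-dimensional exercise-related
correlation pattern; a full copula is deliberately out of scope.

**Two materialisation levels.** `level="dv"` draws outcomes directly (fast;
used for statistical calibration at scale). `level="trace"` uses each
participant's realised outcome draw as the generating parameter of raw
data — an Ornstein–Uhlenbeck CoP process (exact discretisation; per-axis
stationary sd chosen so the expected ellipse area hits the target), a
stride-template gyro trace, and biased/noisy triangle trials — and runs the
actual measurement pipeline to produce the recorded value. Using the
realised draw (not the noise-free target) means the dv-level noise term
represents real inter-individual variation that the latent factor does not
explain, so "true correlation" has the same meaning at both levels. The
LLE outcome stays at the dv level unless `compute_lle` is set, since the
full Rosenstein pipeline per participant is the one expensive stage.

**Gait generator.** Strides are a fixed 3-channel template whose two halves
receive independent Gaussian duration jitter (each sd/√2, truncated at
0.15 s), giving total stride-time sd equal to the configured value while
also varying the within-stride phase structure. This second property
matters: per-stride time normalisation removes pure duration differences,
so a generator that only jittered whole-stride durations would produce
timing-independent stability estimates. With half-stride jitter, higher
timing variability degrades local dynamic stability, as it should. The
dominant sagittal peak sits early in the stride (phase ≈ 0.08), so detected
event intervals carry ≈ 0.93 of the generating stride-time sd — inside the
±20% recovery band the tests enforce, and stated here so the small
systematic shrinkage is not mistaken for a detector bug.

**Magnitudes** (sway ≈ 4–15 cm², stride times ≈ 1.1 s, stride-time sd
20–40 ms, LLE ≈ 0.5–0.8 nats/stride, errors of tens of cm/degrees,
activity of hundreds of min/week) are plausible for paediatric testing and
carry no claim of matching any particular cohort. Outcomes are clipped to
physical ranges (e.g. stance time ≤ 20 s trial cap); clipping is rare at
the default noise levels.

`SynthConfig.null()` removes group offsets, zeroes all loadings, and
equalises outcome means across conditions, putting every test of the
analysis report under its null — the basis of the false-positive
calibration (report-wide fraction of p < 0.05 ≈ 5–6% at n = 14/group).

**What passing tests do not show.** The synthetic traces are stationary,
have Gaussian noise, lack long-range stride-time correlations, postural
drift, turning segments, or sensor artefacts; stride templates are
identical across participants. Recovery results therefore validate the
computational chain, not its robustness to real-world signal pathologies.

## Problem sizes used in validation

Calibration checks use 5000 simulated cohorts for the ANOVA type-I rate,
500 for Pearson CI coverage and Levene's level, 200 cohorts for the
report-wide null fraction, 20 seeds for gait parameter recovery and
jitter ordering, and 500 participants per group for end-to-end latent
correlation recovery — sizes at which the Monte-Carlo bands in the tests
have comfortable margins around their targets.

## Known limitations

* The within-sighted vision analysis uses paired contrasts per factor
  (averaging over the other factor) rather than a full within-within 2×2
  ANOVA; for 2-level factors the tests coincide with the univariate RM
  ANOVA's main effects.
* The sandwich-corrected within-subject tests treat difference scores as
  the unit of analysis; no cluster-robust machinery beyond that is used.
* AMI/FNN auto-selection analyses the sagittal channel only and applies
  the result to all three channels.
* No multiple-testing correction is applied across the correlation family
  (by design, matching the analysis plan the package mirrors).
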