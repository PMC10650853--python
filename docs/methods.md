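# Methods

## Scope and data model

`footvel` analyses per-trial foot-angle time series from instep-mounted
IMUs: three channels (dorsi–plantar flexion D-PF, inversion–eversion IN-EV,
abduction–adduction ABD-ADD, degrees; negative = plantar flexion /
inversion / abduction) sampled uniformly, nominally at 30 Hz for ~20 s per
foot and condition. The device is assumed to export orientation *angles*
(not raw gyroscope rates); angular velocity is always derived by
differentiation and never stored in raw files. Trials travel as plain CSV
with a metadata comment header; a session manifest (CSV or YAML) indexes
the subject × foot × condition cells. Non-finite samples are a hard error
by default; an opt-in repair linearly interpolates gaps of at most two
samples, because at 30 Hz longer gaps span a meaningful fraction of a
stride.

## Stride segmentation

A stride is one full gait cycle delimited by successive maxima of the
sagittal (D-PF) angle; the interior minimum is kept as a landmark. The
max-to-max convention is a deliberate choice: only a full cycle supports
the 0–100% abscissa on which all curves are expressed, and the interior
minimum (the plantar-flexion extreme at the end of stance) remains
available as the secondary event. Peaks are found on the angle signal, not
its derivative, which is noisy at 30 Hz, with two gates: prominence of at
least 0.3 × the signal's peak-to-peak range, and minimum spacing
`min_stride_s` (default 0.4 s; `max_stride_s` default 1.6 s). The defaults
bracket running cadence at 2.5 m/s (~1.3 strides/s). Peak *positions* are
localised on a 3-point moving-average copy of the signal — at 30 Hz a
single noisy sample can otherwise displace a maximum by a sample — while
all cutting happens on the raw samples. Strides whose duration falls
outside [0.5×, 2×] of the trial median are dropped with a logged warning
(transition and deceleration steps); edge cycles are dropped implicitly
because a boundary needs a detected maximum on both sides.

## Time normalisation and velocity curves

Segments are linearly interpolated onto a uniform 101-node 0–100% grid.
101 nodes is the field convention; it makes the 30% and 60% impulse
landmarks exact nodes. Velocity is computed **before** normalisation:
central differences on the raw samples at spacing 1/fs, with second-order
one-sided stencils at segment ends, then interpolation of the velocity
samples onto the grid. Differentiating in the time domain first avoids the
distortion of differentiating in percent domain across variable stride
durations; on noiseless equal-duration strides the two orders of operations
agree to 1e-9 (regression-guarded). No smoothing is applied beyond the
device's own filtering — an optional 3-point moving-average pre-filter
exists but is off by default to avoid double-filtering. Ensemble curves
carry node-wise mean and sample SD (ddof = 1, SD ≡ 0 for n = 1) and are
aggregated stride → subject → group; empty cells are reported, never
imputed.

At 30 Hz a stride is only ~23 samples, so the central-difference estimate
at a node equals the average of the true velocity over a ±1-sample window.
Sharp features narrower than ~2 samples (the synthetic heel-rise burst, for
instance) are attenuated by roughly 25–35%; tests against analytic
sinusoids and the generator's templates therefore use derived
finite-difference error bounds (h²·max|v''| scaled by the stencil
constants) rather than ad-hoc tolerances.

## Impulse metrics and asymmetry

The impulse phase is nodes 30..60 inclusive (31 nodes) of the velocity
curve; its summary is the plain arithmetic mean. The limb-asymmetry index
is computed on magnitudes, `100·(1 − min(|L|,|R|)/max(|L|,|R|))`, so the
sign convention of either limb cannot flip it and the direction of the
imbalance is deliberately not analysed; indices above 15% are flagged.
Group asymmetry is reported two ways and labelled: the index of the group
mean values (`asymmetry_of_means`) and the per-subject index averaged
across subjects (`asymmetry_subject_mean` ± SD). The two differ in general
(Jensen-type inequality) and published tables in this literature mix them.
Condition differences are reported as the magnitude change
`||noFO| − |FO||` with a direction label; exact ties report "decrease" by
convention and are logged.

## Scalar inference

Paired two-sided t tests on per-subject differences, 95% t-based CI,
Cohen's d for paired data (mean/SD of differences) categorised as
insignificant (|d| ≤ 0.2), small (≤ 0.5), medium (≤ 0.8) or large (> 0.8).
The Shapiro–Wilk p-value of the differences is reported as a gate with a
logged caution below 0.05, never an automatic switch to a nonparametric
test. Zero-variance differences or n < 3 raise a degenerate-test error
rather than fabricating p = 1.

## Whole-curve SPM

Curve-level inference is permutation-based rather than random-field-theory
based: subject difference curves are sign-flipped (all 2ⁿ patterns
enumerated when n ≤ 12, otherwise `n_perm` random patterns including the
observed labelling), the critical threshold is the (1 − α) quantile
(upper order statistic) of the max-|t| distribution, and suprathreshold
clusters receive p-values from the permutation distribution of the maximal
suprathreshold run length. Permutation gives exact finite-sample
family-wise control without estimating curve smoothness; simulation checks
in the test suite measure FWE ≈ 0.04–0.05 at α = 0.05 and nominal scalar
type-I error. Zero-variance nodes with zero mean difference contribute
t = 0; identical inputs yield no clusters. Node-wise t values agree with
the scalar paired test at every node to 1e-9. Lowering α can only raise
the threshold and shrink clusters (tested). Each of the three figure
panels (left foot, right foot, both feet pooled by per-subject averaging)
is analysed independently.

## Synthetic gait generator

The generator exists because recordings of this kind are typically not
shareable; it provides exact ground truth for every downstream stage.

Each axis carries a periodic angle template over one cycle, stored as a
truncated Fourier series (K = 32 harmonics) fitted to a velocity shape
assembled from wrapped Gaussian bumps: a foot-slap notch just after
initial contact, an early-stance negative dip (signed velocity minimum at
~20% of the cycle), a sharp positive heel-rise burst (signed maximum at
~35%), a push-off dip with the upward zero crossing of the sagittal
velocity near 60% (end of stance), and a broad swing-phase plateau whose
amplitude is solved so the cycle integrates to zero. All axes share the
phase convention that the sagittal angle maximum sits exactly at 0% — the
boundary the segmenter detects — and the sagittal amplitude strictly
dominates the frontal and transverse axes. The bump placement satisfies
the ordinal constraints the templates are specified by (minimum in 10–30%,
maximum in 30–40%, sagittal zero crossing near 60%); no published numeric
amplitude table exists for these curves, so amplitudes were chosen once to
give a realistic-looking ~34° sagittal excursion with impulse-phase means
in the tens of deg/s.

Trials are synthesised by concatenating cycles: log-normal cycle-duration
multipliers (`stride_time_jitter`, CV, default 0.03) warp each cycle's
clock while preserving its shape in percent domain; log-normal per-stride
amplitude factors (`amplitude_jitter`, CV, default 0.05) and a per-subject
amplitude factor shared across the subject's four cells
(`subject_effect_sd`, default 0.10 — implemented as the SD of a log scale
factor, since a constant angle offset in degrees would vanish under
differentiation and carry no statistical content) provide within- and
between-subject variance; additive white noise on the angles (`noise_sd`,
default 0.5°) models the sensor. Trials start mid-swing (phase 0.5) so
every sagittal maximum is interior to the record, mirroring the discard of
transition steps. Randomness derives from streams keyed by
(seed, subject, foot, condition), so any cell is bit-reproducible
independent of generation order.

Condition (orthosis) effects multiply the template velocity inside the
30–60% window through a cosine-tapered mask (5% taper at each edge, fully
inside the window) and the modified velocity is re-integrated; the
residual nonzero cycle integral appears as a small per-cycle angle drift,
exactly as a genuine change of motion confined to one sub-phase would
produce, and leaves the velocity outside the window untouched. Default
effects (D-PF × 0.98, IN-EV × 1.30, ABD-ADD × 0.86) mirror the magnitude
ratios reported in the condition-comparison literature this package
accompanies; the default left/right imbalance (asymmetry targets 0/20/25%
on the three axes, applied as a left-foot amplitude factor) mirrors the
reported asymmetry levels. Both are plain dictionaries and are set to 1.0
/ 0 in every calibration test.

What the generator does **not** emulate: musculoskeletal dynamics, ground
reaction forces, sensor drift or orientation-fusion error, correlated
(non-white) sensor noise, cadence coupling between feet, or overground vs
treadmill differences. Passing tests therefore demonstrate that the
pipeline recovers known effects from signals with this covariance
structure at 30 Hz — not that the device itself is accurate.

## Numerical and runtime choices

* Trial CSVs serialise floats with `%.17g` and are parsed with
  round-trip-exact float conversion, so write→read is bit-lossless.
* The asymmetry index is computed as `100·(1 − min/max)` so equal
  magnitudes give exactly zero.
* Stochastic validation sizes: effect-recovery uses 100 simulated cohorts
  of 40 subjects (1000 permutations each); scalar type-I error uses 5000
  paired-test replicates at n = 40; SPM family-wise error uses 500
  replicates of smooth-noise difference curves at n = 40 with 1000
  permutations. These sizes keep Monte-Carlo error small relative to the
  acceptance bands while the whole suite runs in a few minutes.
* The pipeline writes a resolved-config snapshot and seeds every
  permutation stream from the run seed, so identical configuration yields
  byte-identical stats JSON.

## Known limitations

* 30 Hz sampling fundamentally limits velocity fidelity: features narrower
  than ~2 samples are attenuated, and absolute peak velocities are
  underestimated; comparisons between conditions measured identically
  remain valid.
* Stride detection assumes a dominant sagittal cycle; it is not a
  foot-strike/toe-off event detector and is untested on walking gait.
* The scalar tests assume approximate normality of paired differences;
  the Shapiro–Wilk gate only reports violations.
* No correction is applied across the three axes; each axis is analysed
  independently, as is conventional in this literature.
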