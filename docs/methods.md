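# Methods

## Signal model

One gait cycle of the shank pitch channel is modeled as a piecewise
raised-cosine waveform in stride-local time: a mid-stance plateau at zero,
a cosine descent (duration `d_pre`, default 120 ms, shortened for small
stance times) into the toe-off trough `a_toeoff`; a cosine rise to the
mid-swing peak `a_midswing`; a cosine fall to the heel-strike trough
`a_heelstrike`; and a cosine recovery (`d_post`, 120 ms) back to the
plateau. Raised-cosine arcs were chosen over straight lines for two
reasons:

- the chord slope between two events equals the configured slope exactly,
  so published event-to-event slopes are realizable;
- both extrema are stationary points, so reading them off a 50 Hz grid
  incurs only second-order error (the trough is additionally snapped onto
  the sampling grid and is read exactly in zero-jitter simulations).

Event placement: the toe-off → mid-swing interval is
`d_up = (a_midswing − a_toeoff)/up_slope` and the toe-off → heel-strike
interval equals the swing time, so stride = swing + stance holds
identically with stance defined heel-strike → next toe-off.

### Why the descending slope is a derived quantity

The five published cycle descriptors (two trough/peak amplitudes, two
chord slopes, swing time) overdetermine this geometry. With the
heel-strike trough pinned above the toe-off trough (toe-off must stay the
global minimum of the cycle, which is how the minimum NAV is defined),
realizing both chord slopes forces a toe-off → heel-strike interval of
≈ 0.354 s for the control column, while the published swing time is
0.389 s; conversely, realizing the published down-slope together with the
published swing time would require a heel-strike trough deeper than
toe-off. Published group means need not satisfy such nonlinear identities
(means of ratios are not ratios of means), so one quantity has to give.
The template honors amplitudes, up-slope and the stride/swing/stance
partition exactly; the descending chord becomes
`(a_heelstrike − a_midswing)/(swing − d_up)` (≈ −2490 deg/s² for the
control preset) and every template reports this realized value
(`CycleTemplate.realized_down_slope`), which round-trip tests use as
ground truth.

The heel-strike trough depth is not published; the default is
`a_heelstrike = 0.85 · a_toeoff`, keeping toe-off the global minimum with
a clear margin.

## Generator

A recording is: `stationary_lead` seconds (default 5 s) of standing
still, a deliberate two-sample synchronization shake (default 500 deg/s on
all axes), the walking segment, and a stationary tail. Constant per-axis
biases (defaults 2, −3, 1.5 deg/s) are applied to the whole recording so
the offset-calibration path does real work; white Gaussian noise (default
SD 5 deg/s) is added to every axis. Stride durations and cycle amplitudes
carry multiplicative unit-mean log-normal jitter (stated CVs, defaults
0.02 and 0.05 — log-normal keeps durations and signs valid). Roll and yaw
channels are independently amplitude-jittered copies of the pitch waveform
scaled by `roll_yaw_fraction` (default 0.25), which makes the pitch axis
dominate the share ratios by construction. The right leg is phase-delayed
by half a stride (reciprocal leg phases). Stride count per leg is
`ceil(corridor_length / (speed · stride_time))` with speed defaulting to
the published group means (1.11 control, 0.84 m/s VN). All randomness
flows from a single integer seed through `numpy.random.SeedSequence`.

Presets reproduce the published parameter columns (healthy, left-lesion,
right-lesion). The published stride and stance times are kept verbatim
and swing is recomputed as stride − stance (the published swing differs by
≤ 0.002 s from the identity, a rounding artifact). The contralateral leg
of a VN walk uses a 50 % blend between the lesion column and the control
column — the study reports asymmetry but prints no contralateral values.
Cohort simulation draws each subject's parameters around their column
with the published between-subject SDs, then reconciles them (stance
clipped to 45–75 % of stride; slopes floored so both arcs fit inside the
swing phase).

### What the generator does not emulate

Real shank gyroscope traces carry within-subject waveform-shape changes
(fatigue, turning artifacts at corridor ends), colored sensor noise,
soft-tissue resonance, and cross-axis coupling that is not a scaled copy
of the pitch channel. Passing tests therefore demonstrate correctness of
the pipeline's logic and its noise robustness at realistic amplitudes —
not performance on pathological real-world waveform shapes.

## Analysis conventions

- **Synchronization**: the shake is the first inter-sample change above
  150 deg/s per sample on any axis — far above what walking produces
  between 20 ms samples (≤ ~110 deg/s incl. noise) and well below a
  deliberate shake. The shake time defines t = 0 when aligning a pair.
- **Calibration**: per-axis means over a ≥ 1 s standing window; the
  window is rejected if any axis SD reaches 10 deg/s.
- **Share epsilon**: shares are undefined where the total absolute
  deviation is below 1 deg/s (segment effectively stationary). Axial
  summaries use the median share per axis over the walking segment.
- **Peak detection**: local maxima with height *and* prominence at least
  0.4 × the 90th percentile of positive samples, ≥ 0.5 s apart. The
  height floor matters: the near-zero mid-stance plateau lies between two
  negative troughs and would otherwise qualify on prominence alone.
- **Events**: toe-off is the minimum between the inter-peak midpoint and
  the peak (the midpoint start keeps the previous cycle's heel-strike
  trough out of the window); heel strike is the first local minimum after
  the peak at most half as shallow as the window's deepest point (noise
  dimples on the steep descent are ignored); mid-stance is the smallest
  |pitch| between heel strike and the next toe-off. A cycle whose events
  violate the ordering or sign structure is skipped and logged, never
  imputed. Event times carry one-sample (20 ms) resolution, which bounds
  duration recovery at one sample and chord-slope recovery at ~2–5 %
  for the presets; amplitude recovery is sub-percent.
- **Walking segment**: first to last detected peak, padded by one mean
  stride, clipped to the recording.
- **Timing variances** (σ² of toe-off and heel-strike times) are computed
  on peak-relative event times, removing the cumulative drift of the
  stride clock. No published-value comparison is attached to them: the
  printed σ² lack units and an alignment convention.
- **Spectrum**: single full-segment Hann periodogram (segments of
  60–110 s; peak location, not estimator variance, is the target),
  frequency grid 1/duration, band 0.3–6 Hz, power normalized to unit band
  sum. The three dominant peaks are the largest by power with ≥ 5 % of
  the maximum in prominence, reported in ascending frequency. When a
  subject's waveform has a weak fundamental Fourier component, the
  selection can return harmonics only (f1 at twice the stride rate) —
  an instability of power-ranked selection that mirrors the ambiguous
  second dominant frequency the study reported for patients.
- **Statistics**: normality via Lilliefors-corrected KS (the plain KS
  with estimated parameters is anti-conservative); variance equality via
  Brown–Forsythe (the robust default in SPSS-style workflows); Fisher LSD
  uses the pooled within-group mean square with N − k df; Dunnett T3 uses
  Welch-type pairwise t referred to the studentized maximum modulus,
  evaluated with the independence approximation `1 − (1 − p)^m`
  (conservative relative to unadjusted Welch). The Mann–Whitney U p-value
  is exact by enumeration for combined n ≤ 20 without ties, otherwise the
  tie-corrected normal approximation. The parameter → test routing is
  frozen (amplitudes, slopes, stride/swing through the omnibus family;
  stance time and stance ratio through MWU + Bonferroni with m = number
  of pairs) and overridable.
- **Cohort unit**: one simulated walk = one subject; group comparisons
  run on the lesion-side leg (controls: left leg, the study's reference
  perspective).

## Problem sizes

Round-trip and recovery checks use 25–30-stride single-leg simulations;
walk-level checks use full 88.8 m corridor walks (~82–95 strides per
leg); the cohort drivers use 20 subjects; the null-calibration of the
routed statistical workflow uses 200 parameter-level cohorts. All are
seconds-scale on one CPU.

## Known limitations

- Event times are sample-quantized; no sub-sample interpolation is
  applied, so durations inherit ±20 ms and chord slopes a few percent of
  quantization error.
- The share ratios use absolute deviations; the sign conventions of roll
  and yaw relative to gait phase are not modeled.
- Only offset zeroing is implemented for calibration; scale-factor
  calibration against a reference sensor is out of scope.
- The generator's VN presets change amplitudes and timing but not
  waveform shape classes (festination, freezing, turning are not
  modeled), and no preset claims to reproduce the elevated, high-variance
  second dominant frequency reported for patients.
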