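# Methods

This note documents the models behind `cfspill`'s synthetic-recording
generator, the measurement conventions of the analysis, the defaults and why
they were chosen, and what the synthetic data can and cannot establish about
real recordings. Times are in ms (t = 0 at the first stimulus), currents in
pA (inward negative), voltages in mV, rates in Hz.

## EPSC model and calibration

Synthetic EPSCs are differences of exponentials,

    I(t) = -A · (e^(-t/τ_d) - e^(-t/τ_r)) / w_max,   t ≥ 0,

normalized so the peak magnitude equals the preset amplitude `epsc_peak`. The
closed-form peak time t_p = τ_r τ_d/(τ_d − τ_r) · ln(τ_d/τ_r) serves as the
oracle for waveform tests.

Preset kinetics are stated as *measured* quantities — the 10–90 % rise time
and the single-exponential decay τ fitted from 90 % of peak — because those
are what the analysis reports. The waveform constants (τ_r, τ_d) are
calibrated at preset construction: τ_r by bisection against the analytic
rise time, τ_d by fixed point against the same exponential fit the analysis
applies. A noiseless generate→analyze round trip is therefore exact up to
the weak fit-window dependence of the decay fit (< 0.3 % at dt = 0.02 ms).

Paired pulses are built by linear summation of a scaled copy on the decaying
tail of the first EPSC. The scale is calibrated numerically so that the
*measured* PPR — second amplitude taken from a local baseline in the 2 ms
before pulse 2, divided by the first amplitude — equals the preset value.
This matches how PPR is measured rather than assuming the tail contribution
is negligible (it is ≲ 0.2 % at a 50-ms interval for the preset τ_d values,
but the calibration removes even that).

Measurement conventions that were open choices:

- rise time is 10–90 % with linear interpolation between samples (a 20–80 %
  convention is available via the `fractions` argument);
- decay is a single-exponential least-squares fit y = A e^(-t/τ) + C starting
  at the 90 %-of-peak falling crossing; on noisy traces the crossing is
  localized on a 0.5-ms boxcar-smoothed copy (the fit itself uses raw
  samples) because the noise-inflated apparent peak otherwise biases the
  fitted τ upward by several percent;
- amplitudes are reported as magnitudes; traces keep physiological sign;
- charge is the trapezoidal integral of the baseline-subtracted current
  magnitude, computed in pA·ms and reported in pA·s where drug-sensitive
  charge is concerned (factor 10⁻³). The antagonist-sensitive charge
  integrates the difference of two aligned traces over a 0–500 ms window by
  default (covering both pulses of a 50-ms pair);
- the all-or-none test demands a slope of normalized amplitude vs intensity
  that is both statistically insignificant (p > 0.05) *and* practically
  small (< 10 % predicted change across the range), plus suprathreshold
  CV < 0.2. The suprathreshold cut is 5× the baseline noise SD because the
  amplitude is an extremum over ~10³ samples, for which the expected
  pure-noise extremum already exceeds 3 SD;
- discrete fiber counting splits sorted amplitudes at gaps > 4× noise SD,
  with failures (< 3× noise SD) forming an excluded zero cluster;
- baseline noise SD is estimated as 1.4826 × the median absolute deviation
  of the pre-stimulus baseline.

## Pacemaker spike-train model

Baseline firing is a stationary gamma-renewal process: ISIs are i.i.d.
Gamma(shape k, mean 1/rate). The default k = 20 (CV ≈ 0.22) represents
pacemaker-like regularity; no ISI dispersion statistic was available to pin
it down, so it is exposed as `isi_shape`. Trains start in equilibrium — the
first event sits at a forward-recurrence time sampled as U·X with X drawn
from the length-biased interval distribution (Gamma(k+1)) — so the
pre-stimulus rate equals the nominal rate from the first bin.

The evoked response adds Poisson(`evoked_count`) spikes per trial at
latencies drawn from a normal distribution truncated at zero.

**Pauses** are modeled as multiplicative thinning of the renewal *intensity*,
not spike deletion: the process is generated in operational time
Λ(t) = ∫ m(s) ds with m = `pause_depth` inside the pause window and 1
elsewhere, then mapped back through Λ⁻¹. Because an equilibrium renewal
process has exactly linear expected count in operational time, the expected
spike deficit is exactly (1 − depth) · rate · duration with no post-pause
rebound — e.g. (6.7 − 3.3) Hz × 93 ms = 0.316 spikes for the pausing-cell
preset, which is what makes the cumulative ratio an *emergent* statistic:
the generator never sees the ratio, yet arithmetic predicts
b/a ≈ (0.46 − 0.316)/0.46 ≈ 0.31, consistent with the population value it is
checked against. The pause onset defaults to 20 ms (just after the evoked
transient) and is a preset field.

**Phase reset** (the intrinsic pause after synaptic drive): when enabled, the
renewal process restarts at the last evoked spike — tonic spikes after that
instant are discarded and regenerated with a fresh full ISI. At pacemaker
rates the next ISI far exceeds the 40-ms added-spike window, so the reset
suppresses essentially all tonic spikes between the evoked spike (latency L)
and 40 ms. The PF/MF spiking presets are therefore keyed to the printed
40-ms added-spike counts through the closed form

    measured(40) = λ - (1 - e^(-λ)) · rate · (40 ms - L),

inverted for the Poisson mean λ at preset construction. Presets without
reset use the printed added-spike count as λ directly.

## The cumulative-ratio procedure

The PSH uses 20-ms bins (fine 0.5-ms bins only for Gaussian peak fitting,
whose half-width is reported as FWHM; σ on request). The PSH is integrated as
a running sum evaluated at right bin edges; an OLS line fitted to the
integral over a 300-ms pre-stimulus window ([−300, 0)) is extrapolated over
the whole record and subtracted. The residual counts stimulus-added spikes:
a at t_init = 20 ms, b as the mean over 600–800 ms, ratio = b/a. A separate
added-spike statistic is read at 40 ms; the two initial windows are never
conflated.

Numerical safeguards: when |a| < 5/n_trials the ratio is division-noise
limited; it is still reported, unclamped (ratios can legitimately be
negative under strong silencing), but flagged `reliable=False` and the
classification becomes "undetermined". Classification is otherwise
non_pause ⇔ ratio > 0.65, with the boundary value assigned to pause.

Pause detection: after the excitation transient (first bin at/after the PSH
peak that has fallen back to ≤ the baseline per-bin probability), the pause
is the longest run of ≥ 2 consecutive bins below 0.75 × baseline; duration
is the run length × bin width and the in-pause rate is the mean bin
probability / bin width. With 20-ms bins, a 93-ms pause that starts at a bin
edge is detected as 100 ms (five bins, the last one partial), and the
in-pause rate is pulled slightly above the generator's thinned rate by the
partial bin — a deliberate property of the binned measurement, not a bug.

First-spike latency averages the first post-stimulus spike per trial; trials
without a qualifying spike are excluded and counted. The qualifying window
defaults to 100 ms, but for evoked-latency recovery on tonically firing
cells the analysis restricts it to the 20-ms initial response window (the
same window the ratio's numerator uses): at ~7 Hz tonic rate, a 100-ms
window would be dominated by tonic spikes in the ~half of trials that carry
no evoked spike. The statistic still mixes a small tonic contribution and
min-of-N selection when several evoked spikes occur, so recovered means sit
within a few percent of the generator latency rather than exactly on it.

## Preset values and derived fields

Presets carry the population values for each pathway/condition: PF
(137 pA, 0.62/3.0 ms, PPR 1.6; 5.6 Hz, latency 3.6 ms), MF (124 pA,
0.49/2.4 ms, PPR 1.05; 5.0 Hz, latency 2.8 ms), CF (34.3 pA, 1.3/7.9 ms,
PPR 0.27; 7.1 Hz, 0.68 evoked spikes, latency 9.1 ms, jitter σ from the
2.1-ms FWHM), the pausing condition (6.7 Hz, 0.46 evoked, pause to 3.3 Hz
for 93 ms), uptake block (amplitude ×1.77, decay ×2.57, 2.0 evoked spikes,
183-ms pause with depth derived from the 0.6 ratio at a = 2.0), and uptake
block + mGluR2 antagonist (1.47 evoked spikes, no pause). Two values are not
published and were chosen once: the uptake-block rise time (2.0 ms; the
blocker slows kinetics) and the antagonist-condition decay (15 ms, below the
blocker-alone 20.3 ms so the difference trace carries positive charge).
Additive EPSC noise defaults to 2 pA.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis assumes:
stationary pre-stimulus firing, additive Gaussian trace noise, independent
trials, a single stereotyped EPSC waveform, and rate-modulated (not
conductance-based) pauses. Passing tests therefore demonstrate that the
*measurement pipeline* is correct and internally consistent — e.g. that the
Methods-style cumulative ratio recovers the value implied by independently
set rate/pause parameters. They do not validate biophysics that the
generator deliberately omits: no membrane or conductance model (mGluR2/GIRK
dynamics are summarized phenomenologically as a rate drop), no glutamate
diffusion or uptake (drug conditions are separate presets, not a transport
model), no trial-to-trial adaptation, no recording drift, and no EPSC
amplitude/latency covariation. Cohort-level numbers are produced by
averaging PSHs over independently seeded simulated cells of identical
parameters, so cell-to-cell parameter heterogeneity is absent unless presets
are varied explicitly.

## Problem sizes and determinism

Single-cell analyses use 500 trials over [−500, 900] ms; cohort statistics
average 10–200 such cells (the acceptance script's choices; a cohort of 200
runs in a few seconds). All randomness flows from per-call
`numpy.random.default_rng` seeds — there is no global RNG state — so every
preset + seed combination is bit-reproducible, and the pipeline stamps each
report with the seed and a SHA-256 hash of its canonical configuration.
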