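"""Synthetic recordings with the statistical structure the analysis assumes.

Two families of surrogate data are produced:

* **EPSC sweeps** — difference-of-exponentials synaptic currents
  ``A (exp(-t/tau_decay) - exp(-t/tau_rise))`` with additive Gaussian noise,
  single pulses, 50-ms paired pulses and intensity series (all-or-none, graded,
  or multi-fiber step recruitment);

* **pacemaker spike trains** — stationary gamma-renewal interspike intervals
  (tonic firing at ~5-7 Hz with low ISI variability), plus a stimulus-evoked
  term (Poisson count of spikes at jittered latencies), an optional pause
  implemented as multiplicative thinning of the renewal intensity, and an
  optional phase reset that restarts the renewal process at the last evoked
  spike.

Named presets key the generator to population values for each afferent pathway
(parallel fiber, mossy fiber, climbing fiber) and pharmacological condition
(control, glutamate-uptake block with TBOA, TBOA plus the mGluR2 antagonist
LY341495).  Preset rise/decay parameters are stated as *measured* kinetics
(10-90% rise time, fitted decay tau) and the underlying waveform time constants
are calibrated numerically so the analysis recovers them exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import optimize

from . import epsc as _epsc
from .containers import ConfigError, SpikeTrain, SweepSet, Trace

__all__ = [
    "GeneratorPreset",
    "StimulusProtocol",
    "preset",
    "preset_names",
    "make_epsc_sweep",
    "make_epsc_intensity_series",
    "make_pacemaker_trains",
    "render_voltage",
    "default_spike_template",
    "dexp_waveform",
    "dexp_peak_time",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneratorPreset:
    """Full parameter set for one simulated cell/condition.

    EPSC fields: ``epsc_peak`` (pA, magnitude; rendered as a negative inward
    deflection), waveform time constants ``epsc_rise_tau``/``epsc_decay_tau``
    (ms), paired-pulse ratio ``ppr`` and additive ``noise_sd`` (pA).

    Spiking fields: tonic ``baseline_rate`` (Hz), gamma ISI ``isi_shape``
    (dimensionless regularity; CV = 1/sqrt(shape)), mean ``evoked_count``
    spikes added per stimulus, evoked latency mean/SD (ms), pause parameters
    (``pause_depth`` = in-pause rate as a fraction of baseline, 1.0 = no pause;
    onset/duration in ms) and the ``phase_reset`` flag.
    """

    name: str
    epsc_peak: float
    epsc_rise_tau: float
    epsc_decay_tau: float
    ppr: float
    noise_sd: float
    baseline_rate: float
    isi_shape: float
    evoked_count: float
    evoked_latency_mean: float
    evoked_latency_sd: float
    pause_depth: float = 1.0
    pause_onset: float = 20.0
    pause_duration: float = 0.0
    phase_reset: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsc_peak < 0:
            raise ValueError("epsc_peak must be >= 0 (magnitude)")
        if self.epsc_rise_tau <= 0 or self.epsc_decay_tau <= 0:
            raise ValueError("time constants must be positive")
        if self.epsc_rise_tau >= self.epsc_decay_tau:
            raise ValueError("rise tau must be smaller than decay tau")
        if not 0.0 <= self.pause_depth <= 1.0:
            raise ValueError("pause_depth must lie in [0, 1]")
        if self.pause_duration < 0 or self.baseline_rate < 0:
            raise ValueError("pause_duration and baseline_rate must be >= 0")
        if self.isi_shape < 1:
            raise ValueError("isi_shape must be >= 1")
        if self.noise_sd < 0 or self.evoked_count < 0 or self.evoked_latency_sd < 0:
            raise ValueError("noise_sd, evoked_count, evoked_latency_sd must be >= 0")


@dataclass
class StimulusProtocol:
    """Stimulus pulse times in ms; the first pulse defines t = 0."""

    pulse_times: tuple[float, ...] = (0.0,)
    intensities: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        pt = tuple(float(t) for t in self.pulse_times)
        if not pt or pt[0] != 0.0:
            raise ValueError("first pulse must define t = 0")
        if any(b <= a for a, b in zip(pt, pt[1:])):
            raise ValueError("pulse_times must be strictly increasing")
        self.pulse_times = pt

    @property
    def inter_pulse_interval(self) -> float | None:
        if len(self.pulse_times) < 2:
            return None
        return self.pulse_times[1] - self.pulse_times[0]


PAIRED_50MS = StimulusProtocol((0.0, 50.0))


# ---------------------------------------------------------------------------
# EPSC waveform and calibration
# ---------------------------------------------------------------------------


def dexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Closed-form time of the difference-of-exponentials maximum."""
    return tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)


def dexp_waveform(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak difference of exponentials, zero for t < 0."""
    t = np.asarray(t, dtype=float)
    tp = dexp_peak_time(tau_rise, tau_decay)
    wmax = math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (np.exp(-t[pos] / tau_decay) - np.exp(-t[pos] / tau_rise)) / wmax
    return out


def _analytic_rise_10_90(tau_rise: float, tau_decay: float) -> float:
    """10-90% rise time of the unit waveform, from root-finding on the closed form."""
    tp = dexp_peak_time(tau_rise, tau_decay)

    def w(t: float) -> float:
        return float(dexp_waveform(np.array([t]), tau_rise, tau_decay)[0])

    t10 = optimize.brentq(lambda t: w(t) - 0.1, 1e-12, tp)
    t90 = optimize.brentq(lambda t: w(t) - 0.9, t10, tp)
    return t90 - t10


def _measured_decay(tau_rise: float, tau_decay: float, dt: float = 0.02) -> float:
    """Fitted decay tau the analysis returns on a dense noiseless waveform."""
    span = 8.0 * tau_decay
    t = np.arange(-20.0, span, dt)
    tr = Trace(-dexp_waveform(t, tau_rise, tau_decay), dt=dt, t0=-20.0)
    return _epsc.decay_tau(tr, (-20.0, 0.0), (0.0, span - dt))


@lru_cache(maxsize=64)
def calibrate_taus(rise_10_90: float, decay_fit_tau: float) -> tuple[float, float]:
    """Waveform (tau_rise, tau_decay) whose measured 10-90% rise and fitted
    single-exponential decay equal the requested values.

    The rise tau is solved by bisection against the analytic rise time; the
    decay tau is refined by fixed point against the same exponential fit the
    analysis uses, so a noiseless round trip is exact by construction.
    """
    tau_d = decay_fit_tau
    tau_r = 0.3 * rise_10_90
    for _ in range(4):
        tau_r = optimize.brentq(
            lambda x: _analytic_rise_10_90(x, tau_d) - rise_10_90,
            1e-4 * tau_d,
            0.999 * tau_d,
        )
        tau_d *= decay_fit_tau / _measured_decay(tau_r, tau_d)
    tau_r = optimize.brentq(
        lambda x: _analytic_rise_10_90(x, tau_d) - rise_10_90,
        1e-4 * tau_d,
        0.999 * tau_d,
    )
    return float(tau_r), float(tau_d)


@lru_cache(maxsize=64)
def _ppr_scale(
    tau_rise: float, tau_decay: float, ppr: float, ipi: float, dt: float
) -> float:
    """Scale of the second EPSC so the *measured* paired-pulse ratio (local
    baseline subtraction, as in the analysis) equals the preset value."""
    t = np.arange(-20.0, ipi + 8.0 * tau_decay, dt)

    def measured(scale: float) -> float:
        y = -(dexp_waveform(t, tau_rise, tau_decay)
              + scale * dexp_waveform(t - ipi, tau_rise, tau_decay))
        tr = Trace(y, dt=dt, t0=-20.0)
        return _epsc.paired_pulse_ratio(tr, (0.0, ipi))

    scale = ppr
    for _ in range(3):
        scale *= ppr / measured(scale)
    return float(scale)


def _render_epscs(
    t: np.ndarray,
    p: GeneratorPreset,
    pulse_times: tuple[float, ...],
    dt: float,
    amplitude: float | None = None,
) -> np.ndarray:
    """Sum of inward (negative) EPSCs at the pulse times, second-and-later
    pulses scaled to reproduce the preset paired-pulse ratio."""
    amp = p.epsc_peak if amplitude is None else amplitude
    y = np.zeros_like(t)
    if amp == 0:
        return y
    for i, pt in enumerate(pulse_times):
        scale = 1.0
        if i > 0:
            ipi = pulse_times[i] - pulse_times[i - 1]
            scale = _ppr_scale(p.epsc_rise_tau, p.epsc_decay_tau, p.ppr, ipi, dt)
        y -= amp * scale * dexp_waveform(t - pt, p.epsc_rise_tau, p.epsc_decay_tau)
    return y


def make_epsc_sweep(
    p: GeneratorPreset,
    proto: StimulusProtocol | None = None,
    dt: float = 0.02,
    duration: float | None = None,
    t_pre: float = 50.0,
    seed: int | None = None,
) -> Trace:
    """One EPSC sweep (current trace) under the preset and stimulus protocol.

    ``duration`` is the post-stimulus span in ms and must cover every pulse
    plus at least five decay time constants (default: eight).  Additive
    Gaussian noise with SD ``p.noise_sd``; deterministic given the seed.
    """
    if proto is None:
        proto = StimulusProtocol((0.0,))
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > 0.1:
        raise ValueError("dt must be <= 0.1 ms")
    last = proto.pulse_times[-1]
    if duration is None:
        duration = last + 8.0 * p.epsc_decay_tau
    if duration < last + 5.0 * p.epsc_decay_tau:
        raise ValueError(
            f"duration {duration} ms too short: needs >= {last + 5 * p.epsc_decay_tau}"
        )
    t = np.arange(-t_pre, duration, dt)
    y = _render_epscs(t, p, proto.pulse_times, dt)
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed if seed is None else seed)
        y = y + rng.normal(0.0, p.noise_sd, t.size)
    return Trace(y, dt=dt, t0=-t_pre, units="pA", kind="current")


def make_epsc_intensity_series(
    p: GeneratorPreset,
    intensities: np.ndarray,
    mode: str = "all_or_none",
    level_amplitudes: np.ndarray | None = None,
    thresholds: np.ndarray | None = None,
    dt: float = 0.05,
    seed: int | None = None,
) -> SweepSet:
    """Single-pulse sweeps over a stimulus-intensity series.

    ``all_or_none`` — zero below threshold, fixed amplitude above (single-fiber
    recruitment); ``graded`` — amplitude rises linearly with intensity
    (multi-fiber synaptic input); ``multi_level`` — amplitude is the cumulative
    sum of ``level_amplitudes`` whose ``thresholds`` are exceeded (step-wise
    recruitment of discrete fibers).
    """
    intensities = np.asarray(intensities, dtype=float)
    if mode == "multi_level":
        if level_amplitudes is None or thresholds is None:
            raise ValueError("multi_level mode requires level_amplitudes and thresholds")
        level_amplitudes = np.asarray(level_amplitudes, dtype=float)
        thresholds = np.asarray(thresholds, dtype=float)
        if level_amplitudes.size != thresholds.size:
            raise ValueError("level_amplitudes and thresholds must have equal length")
        if np.any(np.diff(thresholds) <= 0):
            raise ValueError("thresholds must be sorted increasing")
        amps = np.array(
            [level_amplitudes[thresholds <= i].sum() for i in intensities]
        )
    elif mode == "all_or_none":
        thr = float(thresholds[0]) if thresholds is not None else float(
            np.median(intensities)
        )
        amps = np.where(intensities >= thr, p.epsc_peak, 0.0)
    elif mode == "graded":
        amps = p.epsc_peak * intensities / intensities.max()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(p.seed if seed is None else seed)
    duration = 8.0 * p.epsc_decay_tau
    t = np.arange(-50.0, duration, dt)
    traces = []
    for amp in amps:
        y = _render_epscs(t, p, (0.0,), dt, amplitude=float(amp))
        if p.noise_sd > 0:
            y = y + rng.normal(0.0, p.noise_sd, t.size)
        traces.append(Trace(y, dt=dt, t0=-50.0, units="pA", kind="current"))
    return SweepSet(traces, condition=p.name, intensities=intensities)


# ---------------------------------------------------------------------------
# pacemaker spike trains
# ---------------------------------------------------------------------------


def _lam(t: np.ndarray, onset: float, end: float, depth: float) -> np.ndarray:
    """Cumulative intensity (operational time) of the rate-modulated process,
    with the multiplier equal to ``depth`` inside [onset, end] and 1 elsewhere."""
    t = np.asarray(t, dtype=float)
    out = np.where(t <= onset, t, np.nan)
    mid = (t > onset) & (t <= end)
    out = np.where(mid, onset + depth * (t - onset), out)
    out = np.where(t > end, t - (1.0 - depth) * (end - onset), out)
    return out


def _lam_inv(s: np.ndarray, onset: float, end: float, depth: float) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    s_end = onset + depth * (end - onset)
    out = np.where(s <= onset, s, np.nan)
    mid = (s > onset) & (s <= s_end)
    if depth > 0:
        out = np.where(mid, onset + (s - onset) / depth, out)
    else:
        out = np.where(mid, end, out)
    out = np.where(s > s_end, s + (1.0 - depth) * (end - onset), out)
    return out


def _renewal_spikes(
    rng: np.random.Generator,
    s_start: float,
    s_end: float,
    shape: float,
    scale: float,
    equilibrium: bool,
) -> np.ndarray:
    """Gamma-renewal event times in [s_start, s_end).

    With ``equilibrium=True`` the first event is placed at a forward-recurrence
    time sampled from the stationary distribution (length-biased interval times
    a uniform position), so the process starts in steady state.
    """
    span = s_end - s_start
    if span <= 0:
        return np.empty(0)
    if equilibrium:
        first = s_start + rng.uniform() * rng.gamma(shape + 1.0, scale)
    else:
        first = s_start + rng.gamma(shape, scale)
    if first >= s_end:
        return np.empty(0)
    mean_isi = shape * scale
    out = [first]
    last = first
    while last < s_end:
        n = max(8, int((s_end - last) / mean_isi * 1.5) + 8)
        isis = rng.gamma(shape, scale, n)
        times = last + np.cumsum(isis)
        out.append(times)
        last = times[-1]
    spikes = np.concatenate([np.atleast_1d(x) for x in out])
    return spikes[spikes < s_end]


def _evoked_latencies(rng: np.random.Generator, p: GeneratorPreset) -> np.ndarray:
    n = rng.poisson(p.evoked_count)
    if n == 0:
        return np.empty(0)
    lat = rng.normal(p.evoked_latency_mean, p.evoked_latency_sd, n)
    # truncate at zero by redraw (presets keep the mean several SDs above 0)
    for _ in range(100):
        neg = lat < 0
        if not neg.any():
            break
        lat[neg] = rng.normal(p.evoked_latency_mean, p.evoked_latency_sd, neg.sum())
    return np.abs(lat)


def make_pacemaker_trains(
    p: GeneratorPreset,
    n_trials: int,
    window: tuple[float, float],
    seed: int | None = None,
) -> SpikeTrain:
    """Stimulus-aligned pacemaker spike trains.

    Baseline spikes follow a stationary gamma-renewal process (equilibrium
    start, so the pre-stimulus rate equals ``baseline_rate``).  Each trial adds
    Poisson(``evoked_count``) evoked spikes at truncated-normal latencies.  A
    pause (``pause_depth < 1``) thins the renewal intensity multiplicatively
    over ``[pause_onset, pause_onset + pause_duration]`` via time rescaling;
    with ``phase_reset`` the renewal process restarts at the last evoked spike.
    Deterministic given the seed.
    """
    t_start, t_end = window
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if t_start >= t_end:
        raise ValueError(f"empty window {window}")
    rng = np.random.default_rng(p.seed if seed is None else seed)

    rate = p.baseline_rate / 1000.0  # spikes per ms
    shape = p.isi_shape
    scale = 1.0 / (rate * shape) if rate > 0 else float("inf")
    pausing = p.pause_depth < 1.0 and p.pause_duration > 0
    onset, pend = p.pause_onset, p.pause_onset + p.pause_duration

    def lam(t: float | np.ndarray) -> np.ndarray:
        if not pausing:
            return np.asarray(t, dtype=float)
        return _lam(t, onset, pend, p.pause_depth)

    def lam_inv(s: np.ndarray) -> np.ndarray:
        if not pausing:
            return np.asarray(s, dtype=float)
        return _lam_inv(s, onset, pend, p.pause_depth)

    trials: list[np.ndarray] = []
    for _ in range(n_trials):
        evoked = _evoked_latencies(rng, p)
        evoked = evoked[(evoked >= t_start) & (evoked < t_end)]
        if rate > 0:
            s0, s1 = float(lam(t_start)), float(lam(t_end))
            base_op = _renewal_spikes(rng, s0, s1, shape, scale, equilibrium=True)
            baseline = lam_inv(base_op)
            if p.phase_reset and evoked.size:
                t_reset = float(evoked.max())
                baseline = baseline[baseline <= t_reset]
                s_reset = float(lam(t_reset))
                cont = _renewal_spikes(rng, s_reset, s1, shape, scale, equilibrium=False)
                baseline = np.concatenate([baseline, lam_inv(cont)])
        else:
            baseline = np.empty(0)
        spikes = np.sort(np.concatenate([baseline, evoked]))
        trials.append(spikes[(spikes >= t_start) & (spikes < t_end)])
    return SpikeTrain(trials, window=window)


# ---------------------------------------------------------------------------
# voltage rendering
# ---------------------------------------------------------------------------


def default_spike_template(dt: float, amplitude: float = 80.0) -> Trace:
    """A brief action-potential-like voltage deflection (2 ms, unit = mV)."""
    t = np.arange(0.0, 2.0, dt)
    w = np.exp(-t / 0.45) - np.exp(-t / 0.08)
    w = amplitude * w / w.max()
    return Trace(w, dt=dt, t0=0.0, units="mV", kind="voltage")


def render_voltage(
    st: SpikeTrain,
    trial: int,
    dt: float = 0.05,
    spike_template: Trace | None = None,
    noise_sd: float = 0.0,
    v_rest: float = -55.0,
    seed: int | None = None,
) -> Trace:
    """Voltage trace for one trial: resting baseline plus one template instance
    per spike time plus Gaussian noise.  Overlapping templates are unsupported:
    the template must be shorter than the minimum ISI in the trial."""
    if spike_template is None:
        spike_template = default_spike_template(dt)
    spikes = st.trials[trial]
    if spikes.size >= 2:
        min_isi = float(np.diff(spikes).min())
        tpl_span = spike_template.dt * spike_template.samples.size
        if tpl_span >= min_isi:
            raise ValueError(
                f"template span {tpl_span} ms >= minimum ISI {min_isi} ms"
            )
    t0, t_end = st.window
    n = int(round((t_end - t0) / dt))
    y = np.full(n, v_rest)
    tpl = spike_template.samples
    for ts in spikes:
        i = int(round((ts - t0) / dt))
        j = min(i + tpl.size, n)
        if i < n:
            y[i:j] += tpl[: j - i]
    if noise_sd > 0:
        rng = np.random.default_rng(seed if seed is not None else 0)
        y = y + rng.normal(0.0, noise_sd, n)
    return Trace(y, dt=dt, t0=t0, units="mV", kind="voltage")


# ---------------------------------------------------------------------------
# preset registry
# ---------------------------------------------------------------------------


def _reset_corrected_count(added_40ms: float, rate_hz: float, latency: float) -> float:
    """Evoked count that yields the requested 40-ms added-spike statistic when
    the phase reset is active.

    The reset silences the tonic process from the evoked spike to the end of
    the 40-ms window (the next full gamma ISI far exceeds 40 ms at these
    rates), so the measured statistic is
    ``lambda - (1 - exp(-lambda)) * rate * (40 ms - latency)``; invert by fixed
    point.
    """
    deficit = rate_hz / 1000.0 * (40.0 - latency)
    lam = added_40ms
    for _ in range(60):
        lam = added_40ms + (1.0 - math.exp(-lam)) * deficit
    return lam


# Each entry states measured kinetics (rise_10_90, decay tau) and population
# spiking values; waveform taus are calibrated on first access.
_PRESET_TABLE: dict[str, dict] = {}


def _register() -> None:
    pf = dict(
        epsc_peak=137.0, rise_10_90=0.62, decay=3.0, ppr=1.6, noise_sd=2.0,
        baseline_rate=5.6, evoked_added_40=0.75, evoked_latency_mean=3.6,
        evoked_latency_sd=0.53 / 2.355, phase_reset=True,
    )
    mf = dict(
        epsc_peak=124.0, rise_10_90=0.49, decay=2.4, ppr=1.05, noise_sd=2.0,
        baseline_rate=5.0, evoked_added_40=0.86, evoked_latency_mean=2.8,
        evoked_latency_sd=0.48 / 2.355, phase_reset=True,
    )
    cf = dict(
        epsc_peak=34.3, rise_10_90=1.3, decay=7.9, ppr=0.27, noise_sd=2.0,
        baseline_rate=7.1, evoked_count=0.68, evoked_latency_mean=9.1,
        evoked_latency_sd=2.1 / 2.355,
    )
    # TBOA potentiates the spillover EPSC (177% amplitude, 257% decay) and
    # broadens evoked spiking; TBOA+LY blocks the pause but not the excitation.
    cf_tboa_epsc = dict(
        epsc_peak=34.3 * 1.77, rise_10_90=2.0, decay=7.9 * 2.57, ppr=0.27,
        noise_sd=2.0,
    )
    tboa_pause = dict(
        baseline_rate=6.7, evoked_count=2.0, evoked_latency_mean=9.1,
        evoked_latency_sd=3.0, pause_depth=1.0 - 0.8 / (6.7 * 0.183),
        pause_onset=20.0, pause_duration=183.0,
    )
    _PRESET_TABLE.update(
        pf_ctrl=pf, pf_spike=dict(pf),
        mf_ctrl=mf, mf_spike=dict(mf),
        cf_ctrl=cf, cf_spike=dict(cf),
        cf_nonpause=dict(cf),
        cf_pause_ctrl=dict(
            cf, baseline_rate=6.7, evoked_count=0.46,
            pause_depth=3.3 / 6.7, pause_onset=20.0, pause_duration=93.0,
        ),
        cf_tboa=dict(cf_tboa_epsc, **tboa_pause),
        cf_pause_tboa=dict(cf_tboa_epsc, **tboa_pause),
        cf_tboa_ly=dict(
            cf_tboa_epsc, decay=15.0, baseline_rate=6.7, evoked_count=1.47,
            evoked_latency_mean=9.1, evoked_latency_sd=3.0,
        ),
    )


_register()


def preset_names() -> tuple[str, ...]:
    return tuple(sorted(_PRESET_TABLE))


@lru_cache(maxsize=32)
def preset(name: str, seed: int = 0) -> GeneratorPreset:
    """Fully populated generator preset by name (unknown name is a ConfigError)."""
    try:
        entry = dict(_PRESET_TABLE[name])
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
    tau_r, tau_d = calibrate_taus(entry.pop("rise_10_90"), entry.pop("decay"))
    if "evoked_added_40" in entry:
        entry["evoked_count"] = _reset_corrected_count(
            entry.pop("evoked_added_40"),
            entry["baseline_rate"],
            entry["evoked_latency_mean"],
        )
    return GeneratorPreset(
        name=name,
        epsc_rise_tau=tau_r,
        epsc_decay_tau=tau_d,
        isi_shape=20.0,
        seed=seed,
        **entry,
    )


def preset_with(name: str, seed: int = 0, **overrides) -> GeneratorPreset:
    """A registered preset with selected fields overridden."""
    return replace(preset(name, seed), **overrides)
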