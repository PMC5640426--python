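"""Spike-train quantification for stimulus-aligned tonically firing neurons.

Implements the peristimulus-histogram (PSH) pipeline: PSH construction,
baseline rate, Gaussian fits to the evoked peak, first-spike latency/jitter,
the cumulative spike-probability curve (integrated PSH with an extrapolated
linear baseline subtracted), added-spike counts, the cumulative ratio b/a,
pause detection, and pause / non-pause classification at the 0.65 ratio
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .containers import PSH, CumulativeCurve, SpikeTrain, Trace, UndefinedMetricError

__all__ = [
    "detect_spikes",
    "build_psh",
    "baseline_rate",
    "gaussian_fit_psh",
    "first_spike_latency",
    "cumulative_curve",
    "added_spikes",
    "pause_metrics",
    "classify_response",
    "SpikeMetrics",
    "measure_train",
]

#: cumulative-ratio threshold separating pausing from non-pausing responses
CLASSIFICATION_THRESHOLD = 0.65
#: pause bins must fall below this fraction of the baseline per-bin probability
PAUSE_CRITERION = 0.75
#: |a| below this many spikes per trial makes the ratio unreliable
RATIO_FLOOR_SPIKES = 5.0


def detect_spikes(
    tr: Trace, threshold: float = -20.0, refractory: float = 2.0
) -> np.ndarray:
    """Spike times (ms) as upward threshold crossings separated by >= refractory."""
    if tr.kind != "voltage":
        raise ValueError("spike detection requires a voltage trace")
    y = tr.samples
    up = np.flatnonzero((y[:-1] < threshold) & (y[1:] >= threshold)) + 1
    times = tr.t0 + tr.dt * up
    if times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def build_psh(st: SpikeTrain, bin_width: float = 20.0) -> PSH:
    """Peristimulus histogram: per-bin spike count across trials / n_trials.

    Bins tile the analysis window from its start; a trailing partial bin is
    dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if st.n_trials == 0:
        raise ValueError("spike train has zero trials")
    t0, t1 = st.window
    n_bins = int(np.floor((t1 - t0) / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    edges = t0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(st.all_spikes(), bins=edges)
    return PSH(edges, counts / st.n_trials, st.n_trials)


def baseline_rate(st: SpikeTrain, window: tuple[float, float]) -> float:
    """Mean firing rate (Hz) over a pre-stimulus window across trials."""
    lo, hi = window
    if lo >= hi:
        raise ValueError(f"empty window {window}")
    spikes = st.all_spikes()
    n = int(np.sum((spikes >= lo) & (spikes < hi)))
    return n / (st.n_trials * (hi - lo) / 1000.0)


def gaussian_fit_psh(
    psh: PSH,
    fit_window: tuple[float, float],
    width_as: str = "fwhm",
) -> tuple[float, float, float]:
    """Gaussian + constant baseline fit to the evoked PSH peak.

    Returns ``(peak_probability, center_ms, half_width_ms)`` where the peak
    probability is the fitted maximum (amplitude + baseline) and the width is
    the full width at half maximum of the Gaussian (``width_as="sigma"``
    reports sigma instead).
    """
    centers, prob = psh.bin_centers, psh.probability
    mask = (centers >= fit_window[0]) & (centers < fit_window[1])
    if mask.sum() < 5:
        raise ValueError("fit window must contain at least 5 bins")
    x, y = centers[mask], prob[mask]
    c0 = float(np.mean(y))
    a0 = float(y.max() - c0)
    if a0 <= 0:
        raise UndefinedMetricError("no peak above the mean level in the fit window")
    mu0 = float(x[np.argmax(y)])
    s0 = max(psh.bin_width, 0.1 * (fit_window[1] - fit_window[0]) / 2)

    def model(t, A, mu, sigma, C):
        return A * np.exp(-0.5 * ((t - mu) / sigma) ** 2) + C

    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=(a0, mu0, s0, c0), maxfev=20000
        )
    except RuntimeError as exc:
        raise UndefinedMetricError(f"Gaussian fit did not converge: {exc}") from exc
    A, mu, sigma, C = popt
    sigma = abs(float(sigma))
    if A <= 0 or sigma > (fit_window[1] - fit_window[0]):
        raise UndefinedMetricError("degenerate Gaussian fit (flat or unconstrained)")
    width = sigma if width_as == "sigma" else 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma
    return float(A + C), float(mu), float(width)


def first_spike_latency(
    st: SpikeTrain, max_latency: float = 100.0
) -> tuple[float, float, int]:
    """Across-trial mean and SD of the first post-stimulus spike time.

    Trials with no spike in ``(0, max_latency]`` are excluded; the number of
    excluded trials is returned as the third element.  For evoked-latency
    recovery on tonically firing cells, restrict ``max_latency`` to the evoked
    response window so tonic spikes do not contaminate the statistic.
    """
    firsts = []
    excluded = 0
    for trial in st.trials:
        post = trial[(trial > 0) & (trial <= max_latency)]
        if post.size:
            firsts.append(post[0])
        else:
            excluded += 1
    if not firsts:
        raise UndefinedMetricError("no trial has a qualifying post-stimulus spike")
    firsts = np.asarray(firsts)
    sd = float(np.std(firsts, ddof=1)) if firsts.size > 1 else 0.0
    return float(np.mean(firsts)), sd, excluded


def cumulative_curve(
    psh: PSH,
    baseline_fit_window: tuple[float, float] = (-300.0, 0.0),
    t_init: float = 20.0,
    steady_window: tuple[float, float] = (600.0, 800.0),
) -> CumulativeCurve:
    """Cumulative spike-probability curve and the b/a cumulative ratio.

    The PSH is integrated (running sum of per-bin probabilities, evaluated at
    the right bin edges); an ordinary least-squares line fitted to the integral
    over the pre-stimulus ``baseline_fit_window`` is extrapolated over the
    whole record and subtracted.  The residual counts stimulus-added spikes
    per trial: ``a`` is its value at ``t_init`` (initial added spikes), ``b``
    the mean over ``steady_window`` (steady state), and ``ratio = b/a``.

    When ``|a|`` falls below 5/n_trials the ratio is resolution-limited and the
    curve is flagged unreliable (``reliable=False``); the ratio is still
    reported, unclamped.
    """
    times = psh.bin_edges[1:]
    integral = np.cumsum(psh.probability)
    lo, hi = baseline_fit_window
    if lo >= hi or hi > 0 + 1e-9:
        raise ValueError("baseline_fit_window must be pre-stimulus with start < end")
    mask = (times >= lo) & (times <= hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError("baseline_fit_window must span at least 2 bins")
    slope, intercept = np.polyfit(times[mask], integral[mask], 1)
    added = integral - (slope * times + intercept)

    s_lo, s_hi = steady_window
    if not (times[0] <= t_init <= times[-1]) or s_hi > times[-1] + 1e-9:
        raise ValueError("t_init and steady_window must lie inside the PSH")
    a = float(np.interp(t_init, times, added))
    s_mask = (times >= s_lo) & (times <= s_hi + 1e-9)
    b = float(np.mean(added[s_mask]))
    reliable = abs(a) >= RATIO_FLOOR_SPIKES / psh.n_trials
    ratio = b / a if a != 0 else float("nan")
    return CumulativeCurve(
        times=times,
        added_spikes=added,
        a=a,
        b=b,
        ratio=ratio,
        t_init=t_init,
        steady_window=(s_lo, s_hi),
        n_trials=psh.n_trials,
        reliable=reliable,
        baseline_slope=float(slope),
        baseline_intercept=float(intercept),
    )


def added_spikes(cc: CumulativeCurve, window_end: float = 40.0) -> float:
    """Number of spikes added per stimulus: the cumulative-curve value at
    ``window_end`` ms (default 40 ms)."""
    return cc.value_at(window_end)


def pause_metrics(
    psh: PSH,
    baseline_rate_hz: float,
    search_window: tuple[float, float] = (0.0, 500.0),
    criterion: float = PAUSE_CRITERION,
    min_bins: int = 2,
) -> tuple[float, float]:
    """Duration (ms) and mean rate (Hz) of the post-excitation spike pause.

    After the excitation transient (the first bin at/after the evoked peak
    whose probability has fallen back to or below baseline), the pause is the
    maximal run of consecutive bins with probability below
    ``criterion x baseline``; runs shorter than ``min_bins`` bins do not
    qualify.  Returns ``(0.0, baseline_rate_hz)`` when no run qualifies.
    """
    if baseline_rate_hz <= 0:
        raise ValueError("baseline_rate must be positive")
    base_p = baseline_rate_hz * psh.bin_width / 1000.0
    centers, prob = psh.bin_centers, psh.probability
    mask = (centers >= search_window[0]) & (centers < search_window[1])
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("search window contains no bins")
    p = prob[idx]
    peak = int(np.argmax(p))
    after = np.flatnonzero(p[peak:] <= base_p + 1e-12)
    if after.size == 0:
        return 0.0, baseline_rate_hz
    start = peak + int(after[0])

    below = p[start:] < criterion * base_p
    best_len, best_start, run, run_start = 0, 0, 0, 0
    for i, flag in enumerate(below):
        if flag:
            if run == 0:
                run_start = i
            run += 1
            if run > best_len:
                best_len, best_start = run, run_start
        else:
            run = 0
    if best_len < min_bins:
        return 0.0, baseline_rate_hz
    sel = p[start + best_start : start + best_start + best_len]
    pause_rate = float(np.mean(sel)) / psh.bin_width * 1000.0
    return best_len * psh.bin_width, pause_rate


def classify_response(
    ratio: float,
    threshold: float = CLASSIFICATION_THRESHOLD,
    reliable: bool = True,
) -> str:
    """``"non_pause"`` iff the cumulative ratio exceeds the threshold; exactly
    at threshold counts as ``"pause"``; unreliable ratios are ``"undetermined"``."""
    if not reliable or not np.isfinite(ratio):
        return "undetermined"
    return "non_pause" if ratio > threshold else "pause"


@dataclass
class SpikeMetrics:
    """Per-cell summary of the spike-train analysis."""

    baseline_rate: float
    peak_ap_probability: float
    gauss_halfwidth: float
    latency_mean: float
    latency_sd: float
    added_spikes_20ms: float
    added_spikes_40ms: float
    cumulative_ratio: float
    ratio_reliable: bool
    pause_duration: float
    pause_rate: float
    classification: str


def measure_train(
    st: SpikeTrain,
    bin_width: float = 20.0,
    baseline_window: tuple[float, float] = (-300.0, 0.0),
    t_init: float = 20.0,
    steady_window: tuple[float, float] = (600.0, 800.0),
    latency_window: float = 20.0,
    fine_bin_width: float = 0.5,
    gauss_fit_window: tuple[float, float] = (0.0, 40.0),
    threshold: float = CLASSIFICATION_THRESHOLD,
    pause_criterion: float = PAUSE_CRITERION,
) -> SpikeMetrics:
    """Run the full spike-train pipeline on one cell's trials.

    The coarse (default 20 ms) PSH feeds the cumulative curve and the pause
    detector; a fine-binned PSH (default 0.5 ms) feeds the Gaussian fit of the
    evoked peak.  Initial added spikes are measured both at 20 ms (the ratio's
    numerator convention) and at 40 ms (the added-spike statistic); the two are
    reported separately.
    """
    psh = build_psh(st, bin_width)
    rate = baseline_rate(st, baseline_window)
    cc = cumulative_curve(psh, baseline_window, t_init, steady_window)
    try:
        fine = build_psh(st, fine_bin_width)
        peak_p, _, halfwidth = gaussian_fit_psh(fine, gauss_fit_window)
    except (UndefinedMetricError, ValueError):
        peak_p, halfwidth = float("nan"), float("nan")
    try:
        lat_mean, lat_sd, _ = first_spike_latency(st, latency_window)
    except UndefinedMetricError:
        lat_mean, lat_sd = float("nan"), float("nan")
    dur, prate = pause_metrics(psh, rate, criterion=pause_criterion)
    return SpikeMetrics(
        baseline_rate=rate,
        peak_ap_probability=peak_p,
        gauss_halfwidth=halfwidth,
        latency_mean=lat_mean,
        latency_sd=lat_sd,
        added_spikes_20ms=cc.value_at(min(20.0, cc.times[-1])),
        added_spikes_40ms=added_spikes(cc, 40.0),
        cumulative_ratio=cc.ratio,
        ratio_reliable=cc.reliable,
        pause_duration=dur,
        pause_rate=prate,
        classification=classify_response(cc.ratio, threshold, cc.reliable),
    )
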