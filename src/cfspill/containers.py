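"""Core in-memory containers shared by the generator and the analysis modules.

Conventions used throughout the package:

* time is in **ms**, with ``t = 0`` at the (first) stimulus;
* currents are in **pA** with physiological sign (inward currents are negative
  deflections at a -60 mV holding potential); reported amplitudes are magnitudes;
* voltages are in **mV**.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trace",
    "SweepSet",
    "SpikeTrain",
    "PSH",
    "CumulativeCurve",
    "ConfigError",
    "UndefinedMetricError",
]


class ConfigError(ValueError):
    """Raised for invalid configuration (unknown preset, malformed config file)."""


class UndefinedMetricError(RuntimeError):
    """Raised when a metric is undefined on the given data (e.g. no resolvable peak)."""


@dataclass
class Trace:
    """A uniformly sampled analog signal aligned to the stimulus.

    Parameters
    ----------
    samples : ndarray
        Sample values (pA for currents, mV for voltages).
    dt : float
        Sampling interval in ms.
    t0 : float
        Time of the first sample in ms relative to the stimulus.
    units : str
        Physical units label (``"pA"`` or ``"mV"``).
    kind : str
        ``"current"`` or ``"voltage"``.
    """

    samples: np.ndarray
    dt: float
    t0: float = 0.0
    units: str = "pA"
    kind: str = "current"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.kind not in ("current", "voltage"):
            raise ValueError(f"kind must be 'current' or 'voltage', got {self.kind!r}")

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms relative to the stimulus."""
        return self.t0 + self.dt * np.arange(self.samples.size)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.samples.size - 1)

    def window_values(self, window: tuple[float, float]) -> np.ndarray:
        """Samples with time in ``[window[0], window[1])``; errors if outside the trace."""
        lo, hi = window
        if lo >= hi:
            raise ValueError(f"window start must precede end, got {window}")
        if lo < self.t0 - 0.5 * self.dt or hi > self.t_end + 0.5 * self.dt:
            raise ValueError(
                f"window {window} outside trace span [{self.t0}, {self.t_end}]"
            )
        t = self.time
        mask = (t >= lo - 1e-9) & (t < hi - 1e-9)
        vals = self.samples[mask]
        if vals.size == 0:
            raise ValueError(f"window {window} contains no samples (dt={self.dt})")
        return vals


@dataclass
class SweepSet:
    """Repeated traces recorded under one condition/protocol."""

    traces: list[Trace]
    condition: str = ""
    intensities: np.ndarray | None = None
    pulse_times: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("SweepSet requires at least one trace")
        dts = {tr.dt for tr in self.traces}
        if len(dts) != 1:
            raise ValueError("all traces in a SweepSet must share dt")
        if self.intensities is not None:
            self.intensities = np.asarray(self.intensities, dtype=float)
            if self.intensities.size != len(self.traces):
                raise ValueError("intensities must have one entry per trace")

    @property
    def dt(self) -> float:
        return self.traces[0].dt

    def __len__(self) -> int:
        return len(self.traces)


@dataclass
class SpikeTrain:
    """Per-trial stimulus-aligned spike times over a fixed analysis window."""

    trials: list[np.ndarray]
    window: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.window
        if lo >= hi:
            raise ValueError(f"window start must precede end, got {self.window}")
        clean = []
        for i, tr in enumerate(self.trials):
            arr = np.sort(np.asarray(tr, dtype=float))
            if arr.size and (arr[0] < lo - 1e-9 or arr[-1] > hi + 1e-9):
                raise ValueError(f"trial {i} has spikes outside window {self.window}")
            clean.append(arr)
        self.trials = clean

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def all_spikes(self) -> np.ndarray:
        if not self.trials:
            return np.empty(0)
        return np.concatenate(self.trials) if self.trials else np.empty(0)


@dataclass
class PSH:
    """Peristimulus histogram: per-trial spike probability in contiguous time bins."""

    bin_edges: np.ndarray
    probability: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if self.bin_edges.size != self.probability.size + 1:
            raise ValueError("bin_edges must have one more entry than probability")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must be contiguous and uniform")
        if np.any(self.probability < 0):
            raise ValueError("probability must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class CumulativeCurve:
    """Baseline-subtracted integral of a PSH (cumulative added spikes per trial).

    ``a`` is the initial number of added spikes (curve value at ``t_init``), ``b``
    the steady-state value (mean over ``steady_window``); ``ratio = b / a`` is the
    cumulative ratio used to separate pausing from non-pausing responses.
    """

    times: np.ndarray
    added_spikes: np.ndarray
    a: float
    b: float
    ratio: float
    t_init: float
    steady_window: tuple[float, float]
    n_trials: int
    reliable: bool = True
    baseline_slope: float = field(default=0.0, repr=False)
    baseline_intercept: float = field(default=0.0, repr=False)

    def value_at(self, t: float) -> float:
        """Curve value at time ``t`` (linear interpolation between bin edges)."""
        times = self.times
        if t < times[0] - 1e-9 or t > times[-1] + 1e-9:
            raise ValueError(f"time {t} outside curve span [{times[0]}, {times[-1]}]")
        return float(np.interp(t, times, self.added_spikes))
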