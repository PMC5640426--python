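"""End-to-end reproducible pipeline: simulate -> EPSC metrics -> spike metrics
-> classification -> report.

A :class:`RunConfig` fully determines every output; the report is stamped with
the seed and a hash of the canonical config so identical config+seed reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import epsc, spikes, synth
from .stats import summarize

log = logging.getLogger("cfspill")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (all times in ms, rates in Hz)."""

    seed: int = 0
    outdir: str = "cfspill_out"
    epsc_presets: tuple[str, ...] = ("pf_ctrl", "mf_ctrl", "cf_ctrl", "cf_tboa")
    spike_presets: tuple[str, ...] = (
        "cf_pause_ctrl",
        "cf_tboa_ly",
        "cf_nonpause",
        "pf_spike",
    )
    n_sweeps: int = 10
    n_trials: int = 500
    dt: float = 0.02
    bin_width: float = 20.0
    window: tuple[float, float] = (-500.0, 900.0)
    baseline_window: tuple[float, float] = (-300.0, 0.0)
    t_init: float = 20.0
    steady_window: tuple[float, float] = (600.0, 800.0)
    epsc_baseline: tuple[float, float] = (-50.0, 0.0)
    epsc_search: tuple[float, float] = (0.0, 40.0)
    pulse_times: tuple[float, float] = (0.0, 50.0)
    classification_threshold: float = spikes.CLASSIFICATION_THRESHOLD
    pause_criterion: float = spikes.PAUSE_CRITERION
    preset_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("window", "baseline_window", "steady_window", "epsc_baseline",
                     "epsc_search"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name} start must precede end, got {(lo, hi)}")
        if self.n_trials < 1 or self.n_sweeps < 1:
            raise ValueError("n_trials and n_sweeps must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("window", "baseline_window", "steady_window", "epsc_baseline",
                    "epsc_search", "pulse_times", "epsc_presets", "spike_presets"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _stage(name: str, n_in: int, n_out: int, t0: float) -> None:
    log.info(
        "stage=%s n_in=%d n_out=%d elapsed_s=%.3f", name, n_in, n_out, time.time() - t0
    )


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Execute the full pipeline; returns a dict of output paths."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": cfg.seed, "config_hash": cfg.hash()}

    # --- simulate + analyze EPSC sweeps -----------------------------------
    t0 = time.time()
    proto = synth.StimulusProtocol(cfg.pulse_times)
    epsc_rows = []
    for k, name in enumerate(cfg.epsc_presets):
        p = synth.preset_with(name, **cfg.preset_overrides.get(name, {}))
        for i in range(cfg.n_sweeps):
            tr = synth.make_epsc_sweep(
                p, proto, dt=cfg.dt, seed=cfg.seed + 1000 * k + i
            )
            row = epsc.measure_sweep(
                tr, cfg.epsc_baseline, cfg.epsc_search, cfg.pulse_times
            )
            epsc_rows.append({"condition": name, "sweep": i, **row})
    epsc_df = pd.DataFrame(epsc_rows)
    epsc_csv = out / "epsc_metrics.csv"
    epsc_df.to_csv(epsc_csv, index=False, float_format="%.6g")
    _stage("analyze-epsc", len(cfg.epsc_presets) * cfg.n_sweeps, len(epsc_df), t0)

    # --- simulate + analyze spike trains ----------------------------------
    t0 = time.time()
    spike_rows = []
    for k, name in enumerate(cfg.spike_presets):
        p = synth.preset_with(name, **cfg.preset_overrides.get(name, {}))
        st = synth.make_pacemaker_trains(
            p, cfg.n_trials, cfg.window, seed=cfg.seed + 77_000 + k
        )
        m = spikes.measure_train(
            st,
            bin_width=cfg.bin_width,
            baseline_window=cfg.baseline_window,
            t_init=cfg.t_init,
            steady_window=cfg.steady_window,
            threshold=cfg.classification_threshold,
            pause_criterion=cfg.pause_criterion,
        )
        spike_rows.append({"condition": name, **dataclasses.asdict(m)})
    spike_df = pd.DataFrame(spike_rows)
    spike_csv = out / "spike_metrics.csv"
    spike_df.to_csv(spike_csv, index=False, float_format="%.6g")
    _stage("analyze-spikes", len(cfg.spike_presets), len(spike_df), t0)

    # --- summaries + report ------------------------------------------------
    t0 = time.time()
    summaries = []
    for name, grp in epsc_df.groupby("condition"):
        for metric in ("peak_pA", "rise_ms", "decay_ms", "ppr"):
            vals = grp[metric].dropna()
            if len(vals):
                s = summarize(vals, condition=str(name), metric=metric)
                summaries.append(dataclasses.asdict(s))
    report = {
        **stamp,
        "epsc_summaries": summaries,
        "spike_metrics": spike_rows,
        "classifications": {
            r["condition"]: r["classification"] for r in spike_rows
        },
    }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    _stage("report", len(spike_rows), 1, t0)
    return {
        "epsc_metrics": str(epsc_csv),
        "spike_metrics": str(spike_csv),
        "report": str(report_path),
    }
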