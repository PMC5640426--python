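"""Readers and writers for sweep sets and spike trains.

Sweep sets travel either in an HDF5 container (``/sweeps/<i>`` datasets with
``dt``/``units``/``condition``/``pulse_times`` attributes) or as wide CSV
(first column ``time_ms``, one column per sweep, metadata in ``#`` header
comments).  Spike trains travel as long CSV with ``trial,spike_time_ms``
columns.  Round trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import SpikeTrain, SweepSet, Trace

__all__ = [
    "read_sweepset",
    "write_sweepset",
    "read_spiketrain",
    "write_spiketrain",
    "load_config",
]


# ---------------------------------------------------------------------------
# sweep sets
# ---------------------------------------------------------------------------


def write_sweepset(sw: SweepSet, path: str | Path) -> Path:
    """Write a SweepSet to ``.h5``/``.hdf5`` or wide ``.csv`` by extension."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            g = f.create_group("sweeps")
            g.attrs["dt"] = sw.dt
            g.attrs["units"] = sw.traces[0].units
            g.attrs["kind"] = sw.traces[0].kind
            g.attrs["t0"] = sw.traces[0].t0
            g.attrs["condition"] = sw.condition
            g.attrs["pulse_times"] = list(sw.pulse_times)
            if sw.intensities is not None:
                g.attrs["intensities"] = sw.intensities
            for i, tr in enumerate(sw.traces):
                g.create_dataset(str(i), data=tr.samples)
    elif path.suffix == ".csv":
        tr0 = sw.traces[0]
        with open(path, "w") as f:
            f.write(f"# dt={tr0.dt}\n# units={tr0.units}\n# kind={tr0.kind}\n")
            f.write(f"# condition={sw.condition}\n")
            f.write(f"# pulse_times={','.join(str(t) for t in sw.pulse_times)}\n")
            if sw.intensities is not None:
                f.write(
                    f"# intensities={','.join(str(v) for v in sw.intensities)}\n"
                )
            df = pd.DataFrame({"time_ms": tr0.time})
            for i, tr in enumerate(sw.traces):
                df[f"sweep_{i}"] = tr.samples
            df.to_csv(f, index=False)
    else:
        raise ValueError(f"unsupported sweepset extension {path.suffix!r}")
    return path


def _read_csv_header(path: Path) -> dict[str, str]:
    meta = {}
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    return meta


def read_sweepset(path: str | Path) -> SweepSet:
    """Read a SweepSet written by :func:`write_sweepset`."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            g = f["sweeps"]
            for field in ("dt", "units"):
                if field not in g.attrs:
                    raise ValueError(f"sweepset file missing metadata field {field!r}")
            dt = float(g.attrs["dt"])
            units = str(g.attrs["units"])
            kind = str(g.attrs.get("kind", "current"))
            t0 = float(g.attrs.get("t0", 0.0))
            condition = str(g.attrs.get("condition", ""))
            pulse_times = tuple(float(t) for t in g.attrs.get("pulse_times", [0.0]))
            intensities = g.attrs.get("intensities")
            keys = sorted(g.keys(), key=int)
            traces = [
                Trace(g[k][...], dt=dt, t0=t0, units=units, kind=kind) for k in keys
            ]
        return SweepSet(
            traces,
            condition=condition,
            intensities=None if intensities is None else np.asarray(intensities),
            pulse_times=pulse_times,
        )
    if path.suffix == ".csv":
        meta = _read_csv_header(path)
        for field in ("dt", "units"):
            if field not in meta:
                raise ValueError(f"sweepset CSV missing metadata field {field!r}")
        df = pd.read_csv(path, comment="#")
        if "time_ms" not in df.columns:
            raise ValueError("sweepset CSV missing required 'time_ms' column")
        dt = float(meta["dt"])
        t0 = float(df["time_ms"].iloc[0])
        kind = meta.get("kind", "current")
        traces = [
            Trace(df[c].to_numpy(), dt=dt, t0=t0, units=meta["units"], kind=kind)
            for c in df.columns
            if c != "time_ms"
        ]
        intensities = None
        if "intensities" in meta and meta["intensities"]:
            intensities = np.array([float(v) for v in meta["intensities"].split(",")])
        pulse_times = tuple(
            float(v) for v in meta.get("pulse_times", "0.0").split(",")
        )
        return SweepSet(
            traces,
            condition=meta.get("condition", ""),
            intensities=intensities,
            pulse_times=pulse_times,
        )
    raise ValueError(f"unsupported sweepset extension {path.suffix!r}")


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------


def write_spiketrain(st: SpikeTrain, path: str | Path) -> Path:
    """Write a SpikeTrain to long CSV (``trial,spike_time_ms``); the analysis
    window and trial count are preserved in ``#`` header comments so that
    trials without spikes survive the round trip."""
    path = Path(path)
    rows = [
        (i, t) for i, trial in enumerate(st.trials) for t in trial
    ]
    with open(path, "w") as f:
        f.write(f"# window={st.window[0]},{st.window[1]}\n")
        f.write(f"# n_trials={st.n_trials}\n")
        pd.DataFrame(rows, columns=["trial", "spike_time_ms"]).to_csv(f, index=False)
    return path


def read_spiketrain(path: str | Path) -> SpikeTrain:
    """Read a spike-time CSV.  Trial indices are remapped to contiguous 0..n-1;
    non-numeric rows raise with the offending line number."""
    path = Path(path)
    meta = _read_csv_header(path)
    df = pd.read_csv(path, comment="#")
    for col in ("trial", "spike_time_ms"):
        if col not in df.columns:
            raise ValueError(f"spike-time CSV missing required column {col!r}")
    bad = df[
        ~df["spike_time_ms"].apply(np.isreal) | df["spike_time_ms"].isna()
    ]
    if len(bad):
        raise ValueError(f"non-numeric spike time at data line {bad.index[0] + 2}")
    n_trials = int(meta["n_trials"]) if "n_trials" in meta else None
    if df.empty and n_trials in (None, 0):
        raise ValueError("spike-time CSV contains no trials")
    if "window" in meta:
        lo, hi = (float(v) for v in meta["window"].split(","))
    else:
        lo = float(min(df["spike_time_ms"].min(), 0.0)) if len(df) else 0.0
        hi = float(df["spike_time_ms"].max()) + 1.0 if len(df) else 1.0
    ids = sorted(df["trial"].unique())
    if n_trials is not None:
        # trust the recorded trial indices so spike-free trials survive
        if ids and (min(ids) < 0 or max(ids) >= n_trials):
            raise ValueError("trial index outside recorded n_trials")
        remap = {orig: int(orig) for orig in ids}
        n = n_trials
    else:
        remap = {orig: i for i, orig in enumerate(ids)}
        n = len(ids)
    trials: list[np.ndarray] = [np.empty(0) for _ in range(n)]
    for orig, grp in df.groupby("trial"):
        trials[remap[orig]] = np.sort(grp["spike_time_ms"].to_numpy(dtype=float))
    return SpikeTrain(trials, window=(lo, hi))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
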