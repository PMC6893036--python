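"""Session container I/O.

A *session* is an HDF5 file with one group per channel::

    /velocity      data, attrs: rate, t0, units
    /lfp           ...
    /decays        data (n_records x n_samples), timestamps, attrs: rate
    /truth         JSON ground-truth sidecar is written next to the file

plus CSV round trips for time series and event tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import EVENT_COLUMNS, TimeSeries, validate_event_table

__all__ = [
    "write_session",
    "read_session",
    "timeseries_to_csv",
    "timeseries_from_csv",
    "events_to_csv",
    "events_from_csv",
    "load_yaml",
]


def write_session(path, channels: dict, decays=None, decay_timestamps=None,
                  decay_rate: float | None = None, truth: dict | None = None) -> None:
    """Write channels (name -> TimeSeries) and optional decay records to HDF5.

    ``truth``, when given, is written as a JSON sidecar ``<path>.truth.json``.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, ts in channels.items():
            g = f.create_group(name)
            g.create_dataset("data", data=ts.values)
            g.attrs["rate"] = float(ts.rate)
            g.attrs["t0"] = float(ts.t0)
            g.attrs["units"] = ts.units
        if decays is not None:
            g = f.create_group("decays")
            g.create_dataset("data", data=np.asarray(decays))
            g.create_dataset("timestamps", data=np.asarray(decay_timestamps))
            g.attrs["rate"] = float(decay_rate if decay_rate else 0.0)
    if truth is not None:
        sidecar = path.with_suffix(path.suffix + ".truth.json")
        sidecar.write_text(json.dumps(truth, indent=2, default=_json_default))


def read_session(path) -> dict:
    """Read a session container; returns {name: TimeSeries} plus decays."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        for name, g in f.items():
            if name == "decays":
                out["decays"] = np.asarray(g["data"])
                out["decay_timestamps"] = np.asarray(g["timestamps"])
                out["decay_rate"] = float(g.attrs.get("rate", 0.0))
                continue
            out[name] = TimeSeries(
                np.asarray(g["data"]), float(g.attrs["rate"]),
                float(g.attrs.get("t0", 0.0)), str(g.attrs.get("units", "")))
    return out


def timeseries_to_csv(ts: TimeSeries, path) -> None:
    pd.DataFrame({"time": ts.times, "value": ts.values}).to_csv(path, index=False)


def timeseries_from_csv(path, units: str = "") -> TimeSeries:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    if len(t) < 2:
        raise ValueError("need at least two samples to infer the rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("CSV time stamps are not uniformly spaced")
    return TimeSeries(df["value"].to_numpy(), 1.0 / dt[0], t0=float(t[0]), units=units)


def events_to_csv(df: pd.DataFrame, path) -> None:
    validate_event_table(df)
    df.loc[:, list(EVENT_COLUMNS)].to_csv(path, index=False)


def events_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_event_table(df)
    return df


def load_yaml(path) -> dict:
    with open(path) as f:
        out = yaml.safe_load(f)
    return {} if out is None else out


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
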