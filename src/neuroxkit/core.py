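"""Core containers shared by every analysis stage.

All channels are uniformly sampled :class:`TimeSeries`; behavioural state
is a :class:`BinarySeries`; detected locomotion/rest epochs live in a
pandas ``DataFrame`` with the :data:`EVENT_COLUMNS` schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "BinarySeries",
    "EVENT_COLUMNS",
    "make_event_table",
    "validate_event_table",
]


@dataclass
class TimeSeries:
    """A uniformly sampled channel.

    Parameters
    ----------
    values : array
        Sample values. Must be finite.
    rate : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Time of the first sample in seconds.
    units : str
        Physical units of the samples (informational).
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if self.values.size == 0:
            raise ValueError("TimeSeries must contain at least one sample")
        if not np.isfinite(self.values).all():
            raise ValueError("TimeSeries values must be finite")
        if not (self.rate > 0):
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / rate)."""
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def copy(self, **changes) -> "TimeSeries":
        out = replace(self, **changes)
        if "values" not in changes:
            out.values = self.values.copy()
        return out

    def crop(self, start: float, stop: float) -> "TimeSeries":
        """Return the samples with times in [start, stop)."""
        i0 = max(0, int(np.ceil((start - self.t0) * self.rate - 1e-9)))
        i1 = min(self.n, int(np.ceil((stop - self.t0) * self.rate - 1e-9)))
        if i1 <= i0:
            raise ValueError("empty crop window")
        return TimeSeries(self.values[i0:i1], self.rate,
                          self.t0 + i0 / self.rate, self.units)


@dataclass
class BinarySeries:
    """A 0/1 state indicator sampled at a fixed rate (e.g. locomotion)."""

    delta: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.delta)
        if not np.isin(d, (0, 1)).all():
            raise ValueError("BinarySeries values must be 0 or 1")
        self.delta = d.astype(np.uint8)
        if not (self.rate > 0):
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.delta.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def runs(self) -> list[tuple[int, int]]:
        """Contiguous runs of ones as half-open sample index pairs."""
        d = np.concatenate(([0], self.delta, [0]))
        edges = np.flatnonzero(np.diff(d.astype(np.int8)))
        return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


EVENT_COLUMNS = ("onset", "offset", "kind", "duration")


def make_event_table(onsets, offsets, kind: str) -> pd.DataFrame:
    onsets = np.asarray(onsets, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    df = pd.DataFrame({
        "onset": onsets,
        "offset": offsets,
        "kind": kind,
        "duration": offsets - onsets,
    })
    validate_event_table(df)
    return df


def validate_event_table(df: pd.DataFrame) -> None:
    """Check the event-table invariants; raise ValueError on violation."""
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")
    if len(df) == 0:
        return
    if (df["offset"] <= df["onset"]).any():
        raise ValueError("event offsets must exceed onsets")
    for _, grp in df.groupby("kind", sort=False):
        on = grp["onset"].to_numpy()
        off = grp["offset"].to_numpy()
        if len(on) > 1 and not (np.diff(on) > 0).all():
            raise ValueError("event onsets must be strictly increasing within a kind")
        if len(on) > 1 and (off[:-1] > on[1:]).any():
            raise ValueError("events of one kind must not overlap")
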