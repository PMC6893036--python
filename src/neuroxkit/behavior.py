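"""Locomotion detection and session segmentation.

Treadmill velocity is low-passed (10 Hz, 5th-order Butterworth),
differentiated, and thresholded on |acceleration| >= a_c (3 cm/s^2 by
default) to give a binary locomotion indicator; evoked events and rest
intervals are then cut out of that indicator under the pre-rest /
minimum-duration rules used throughout the analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .core import BinarySeries, TimeSeries, make_event_table

__all__ = ["binarize_locomotion", "segment_events", "rest_periods",
           "resample_binary"]


def binarize_locomotion(velocity: TimeSeries, lp_cutoff: float = 10.0,
                        a_c: float = 3.0, order: int = 5) -> BinarySeries:
    """Binarize treadmill motion: delta = 1 where |acceleration| >= a_c.

    Velocity (cm/s) is zero-phase low-passed at ``lp_cutoff`` then
    differentiated by central differences; the threshold comparison is
    inclusive (equality counts as locomotion).
    """
    if velocity.rate <= 2 * lp_cutoff:
        raise ValueError("velocity rate must exceed twice the low-pass cutoff")
    sos = signal.butter(order, lp_cutoff, btype="low", fs=velocity.rate, output="sos")
    v = signal.sosfiltfilt(sos, velocity.values)
    a = np.gradient(v) * velocity.rate  # cm/s^2, central differences
    return BinarySeries((np.abs(a) >= a_c).astype(np.uint8),
                        velocity.rate, velocity.t0)


def _merged_runs(delta: BinarySeries, merge_gap: float) -> list[tuple[int, int]]:
    runs = delta.runs()
    if not runs or merge_gap <= 0:
        return runs
    gap_n = merge_gap * delta.rate
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap_n:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(r) for r in merged]


def segment_events(delta: BinarySeries, min_pre_rest: float = 3.0,
                   min_loco: float = 5.0, merge_gap: float = 0.5) -> pd.DataFrame:
    """Locomotion events eligible for triggered analyses.

    A merged locomotion run qualifies iff it is preceded by at least
    ``min_pre_rest`` seconds with no locomotion and lasts at least
    ``min_loco`` seconds (raise ``min_loco`` to 10 s for oxygen analyses).
    Runs separated by gaps shorter than ``merge_gap`` are bridged first.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    runs = _merged_runs(delta, merge_gap)
    onsets, offsets = [], []
    prev_end = 0
    for s, e in runs:
        pre_ok = (s - prev_end) >= min_pre_rest * delta.rate and s >= min_pre_rest * delta.rate
        if pre_ok and (e - s) >= min_loco * delta.rate:
            onsets.append(delta.t0 + s / delta.rate)
            offsets.append(delta.t0 + e / delta.rate)
        prev_end = e
    return make_event_table(onsets, offsets, "locomotion")


def rest_periods(delta: BinarySeries, post_gap: float = 4.0,
                 min_dur: float = 10.0, merge_gap: float = 0.5) -> pd.DataFrame:
    """Rest intervals: start ``post_gap`` seconds after each locomotion run
    ends and stop at the next run's onset; only intervals of at least
    ``min_dur`` seconds are kept (30 s for resting cross-correlations).

    Session boundaries count as rest boundaries, so an all-quiet record
    yields one interval covering the whole session.
    """
    runs = _merged_runs(delta, merge_gap)
    t_end = delta.t0 + delta.n / delta.rate
    starts, stops = [], []
    prev_end_t = delta.t0  # session start counts as a rest boundary (no post gap)
    first = True
    for s, e in runs:
        cand_start = prev_end_t if first else prev_end_t + post_gap
        cand_stop = delta.t0 + s / delta.rate
        if cand_stop - cand_start >= min_dur:
            starts.append(cand_start)
            stops.append(cand_stop)
        prev_end_t = delta.t0 + e / delta.rate
        first = False
    cand_start = prev_end_t if first else prev_end_t + post_gap
    if t_end - cand_start >= min_dur:
        starts.append(cand_start)
        stops.append(t_end)
    return make_event_table(starts, stops, "rest")


def resample_binary(delta: BinarySeries, out_rate: float) -> BinarySeries:
    """Nearest-neighbour resampling of a binary indicator to ``out_rate``
    (used to align 1 kHz locomotion with 30 Hz oxygen)."""
    n_out = int(round(delta.n * out_rate / delta.rate))
    idx = np.minimum((np.arange(n_out) * delta.rate / out_rate).round().astype(int),
                     delta.n - 1)
    return BinarySeries(delta.delta[idx], out_rate, delta.t0)
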