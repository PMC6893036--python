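"""Calibration, drift correction, filtering and resampling of raw channels.

All filters are zero-phase (forward-backward application), which preserves
the event timing that triggered averages and kernel fits depend on. The
polarographic electrode's ~0.3 s response time is deliberately *not*
deconvolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import TimeSeries

__all__ = ["ElectrodeCalibration", "drift_correct", "lowpass_downsample", "bandpass"]


@dataclass
class ElectrodeCalibration:
    """Two-point (zero / air-saturated) electrode calibrations taken before
    and after the recording, used for linear drift correction.

    Currents are in the amplifier's native units; ``sat_mmHg`` is the oxygen
    tension of the air-saturated calibration solution (default 159.6 mmHg,
    0.21 x 760).
    """

    pre_zero: float
    pre_sat: float
    post_zero: float
    post_sat: float
    t_pre: float
    t_post: float
    sat_mmHg: float = 0.21 * 760.0
    temperature: float = 37.0

    def __post_init__(self) -> None:
        if self.pre_sat <= self.pre_zero or self.post_sat <= self.post_zero:
            raise ValueError("saturated reading must exceed zero reading")
        if self.t_post <= self.t_pre:
            raise ValueError("post-calibration must follow pre-calibration")


def drift_correct(raw: TimeSeries, cal: ElectrodeCalibration) -> TimeSeries:
    """Convert electrode current to mmHg, linearly interpolating the
    zero/span calibration between the pre- and post-experiment points.

    The recording window must lie between the two calibration timestamps.
    """
    t = raw.times
    if t[0] < cal.t_pre - 1e-9 or t[-1] > cal.t_post + 1e-9:
        raise ValueError("recording extends outside the calibration interval")
    frac = (t - cal.t_pre) / (cal.t_post - cal.t_pre)
    zero = cal.pre_zero + frac * (cal.post_zero - cal.pre_zero)
    span = (cal.pre_sat - cal.pre_zero) + frac * (
        (cal.post_sat - cal.post_zero) - (cal.pre_sat - cal.pre_zero))
    if (span <= 0).any():
        raise ValueError("interpolated calibration span is non-positive")
    mmhg = (raw.values - zero) / span * cal.sat_mmHg
    return TimeSeries(mmhg, raw.rate, raw.t0, units="mmHg")


def lowpass_downsample(ts: TimeSeries, cutoff: float, order: int = 5,
                       out_rate: float | None = None) -> TimeSeries:
    """Zero-phase Butterworth low-pass, then anti-aliased decimation.

    Mirrors the oxygen-channel preprocessing (1 Hz, 5th order, down to
    30 Hz). DC gain is exactly 1; decimation uses polyphase resampling so
    arbitrary rational rate ratios are safe.
    """
    if cutoff >= ts.rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz at or above Nyquist ({ts.rate / 2} Hz)")
    if out_rate is not None and out_rate > ts.rate:
        raise ValueError("out_rate must not exceed the input rate")
    sos = signal.butter(order, cutoff, btype="low", fs=ts.rate, output="sos")
    y = signal.sosfiltfilt(sos, ts.values)
    rate = ts.rate
    if out_rate is not None and out_rate != ts.rate:
        frac = Fraction(out_rate / ts.rate).limit_denominator(10000)
        y = signal.resample_poly(y, frac.numerator, frac.denominator, padtype="line")
        rate = ts.rate * frac.numerator / frac.denominator
    return TimeSeries(y, rate, ts.t0, ts.units)


def bandpass(ts: TimeSeries, lo: float, hi: float, order: int = 5,
             design: str = "butterworth") -> TimeSeries:
    """Zero-phase band-limited filtering.

    ``lo = 0`` gives a pure low-pass (used for the 5 Hz Bessel smoothing of
    MUA rates and the 30 Hz thermocouple conditioning). Designs: 5th-order
    Butterworth (default) or Bessel.
    """
    if not (0 <= lo < hi < ts.rate / 2):
        raise ValueError(f"invalid band ({lo}, {hi}) Hz at rate {ts.rate} Hz")
    if design not in ("butterworth", "bessel"):
        raise ValueError(f"unknown filter design {design!r}")
    maker = signal.butter if design == "butterworth" else signal.bessel
    if lo == 0:
        sos = maker(order, hi, btype="low", fs=ts.rate, output="sos")
    else:
        sos = maker(order, [lo, hi], btype="band", fs=ts.rate, output="sos")
    return TimeSeries(signal.sosfiltfilt(sos, ts.values), ts.rate, ts.t0, ts.units)
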