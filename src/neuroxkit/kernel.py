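"""Hemodynamic / neural response function estimation by linear deconvolution.

The observed signal V (tissue oxygen or gamma power, at the common 30 Hz
analysis rate) is modeled as a linear, time-invariant response to the
binarized locomotion regressor n(t):

    V = L H,   L = [1 | lagged copies of n]

with H estimated by least squares. The normal-equation form is solved via
QR/pseudoinverse rather than an explicit Gram inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinarySeries, TimeSeries

__all__ = ["Kernel", "build_design", "deconvolve", "kernel_metrics"]


@dataclass
class Kernel:
    """Lag-indexed impulse response with its intercept and summary metrics."""

    lags: np.ndarray          # seconds, starting at 0
    values: np.ndarray        # response per unit locomotion
    intercept: float
    rate: float
    residual_norm: float = np.nan
    metrics: dict = field(default_factory=dict)


def build_design(delta: BinarySeries, k: int) -> np.ndarray:
    """Toeplitz design matrix: an intercept column of ones followed by k
    progressively delayed copies of the locomotion regressor (zero-padded
    at the record start, no wraparound). Shape (n, k + 1)."""
    n = delta.n
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k ({k}) must be smaller than the record length ({n})")
    x = delta.delta.astype(float)
    L = np.zeros((n, k + 1))
    L[:, 0] = 1.0
    for j in range(k):
        L[j:, j + 1] = x[:n - j]
    return L


def deconvolve(V: TimeSeries, L: np.ndarray) -> Kernel:
    """Least-squares kernel estimate H from V ~ L H.

    The first coefficient is reported as the intercept, the rest as the
    kernel proper. Raises if the design is rank-deficient (e.g. a record
    with no locomotion at all).
    """
    if L.shape[0] != V.n:
        raise ValueError(f"design has {L.shape[0]} rows but signal has {V.n} samples")
    rank = np.linalg.matrix_rank(L)
    if rank < L.shape[1]:
        raise ValueError(
            "rank-deficient design (insufficient locomotion events for the "
            f"requested kernel length: rank {rank} < {L.shape[1]})")
    H, res, *_ = np.linalg.lstsq(L, V.values, rcond=None)
    resid = float(np.linalg.norm(V.values - L @ H))
    k = L.shape[1] - 1
    kern = Kernel(lags=np.arange(k) / V.rate, values=H[1:], intercept=float(H[0]),
                  rate=V.rate, residual_norm=resid)
    try:
        kern.metrics = kernel_metrics(kern)
    except ValueError:
        kern.metrics = {}
    return kern


def kernel_metrics(kern: Kernel, onset_frac: float = 0.1) -> dict:
    """Summary metrics of a response kernel.

    peak_amplitude is the extremal value of the dominant lobe (sign-aware),
    peak_time its lag, and onset_time the first lag at which the kernel
    crosses ``onset_frac`` of the peak amplitude in the peak's direction.
    """
    v = kern.values
    if v.size == 0 or np.allclose(v, 0):
        raise ValueError("all-zero kernel: metrics undefined")
    ipk = int(np.argmax(np.abs(v)))
    peak = float(v[ipk])
    sign = np.sign(peak)
    crossing = np.flatnonzero(sign * v >= onset_frac * abs(peak))
    onset = float(kern.lags[crossing[0]])
    return {"peak_amplitude": peak, "peak_time": float(kern.lags[ipk]),
            "onset_time": onset}
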