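"""Coupling statistics: cross-correlation with surrogate significance,
ordinary and partial coherence, band-resolved cross-correlograms, and the
exact Wilcoxon signed-rank test used for paired inference.

Coherence is estimated from multitaper cross-spectra averaged over
non-overlapping segments; partial coherence removes from both signals the
component linearly predictable from a third channel:

    C2_xy  = |S_xy|^2 / (S_x S_y)
    PC2_xy.z = |S_xy S_zz - S_xz S_zy|^2
               / ((S_xx S_zz - |S_xz|^2)(S_yy S_zz - |S_yz|^2))
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import TimeSeries
from .preproc import bandpass

__all__ = ["CrossCorrelation", "CoherenceResult", "xcorr", "surrogate_ci",
           "coherence", "partial_coherence", "band_crosscorrelogram",
           "wilcoxon_exact"]


@dataclass
class CrossCorrelation:
    lags: np.ndarray       # seconds; positive lag: x lags y
    r: np.ndarray
    peak_r: float
    peak_lag: float
    ci95: np.ndarray | None = None   # (2, n_lags) surrogate band


@dataclass
class CoherenceResult:
    freqs: np.ndarray
    c2: np.ndarray
    pc2: np.ndarray | None = None
    n_estimates: int = 0
    spectra: dict = field(default_factory=dict)


def _prep_pair(x: TimeSeries, y: TimeSeries, lp: float | None):
    if x.rate != y.rate:
        raise ValueError("inputs must share a sampling rate")
    n = min(x.n, y.n)
    xv, yv = x.values[:n], y.values[:n]
    if lp is not None and lp < x.rate / 2:
        xv = bandpass(TimeSeries(xv, x.rate), 0.0, lp).values
        yv = bandpass(TimeSeries(yv, y.rate), 0.0, lp).values
    xv = xv - xv.mean()
    yv = yv - yv.mean()
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero-variance input")
    return xv, yv


def _norm_xcorr(xv: np.ndarray, yv: np.ndarray, max_n: int) -> np.ndarray:
    """r(l) = sum_t x(t) y(t+l) / sqrt(sum x^2 sum y^2), l in [-max_n, max_n]."""
    n = xv.size
    full = signal.correlate(yv, xv, mode="full", method="fft")
    denom = np.sqrt((xv**2).sum() * (yv**2).sum())
    center = n - 1
    return full[center - max_n:center + max_n + 1] / denom


def xcorr(x: TimeSeries, y: TimeSeries, max_lag: float, lp: float | None = 1.0) -> CrossCorrelation:
    """Normalized cross-correlation over +/- max_lag seconds.

    Both inputs are low-passed (1 Hz by default) and mean-removed first.
    Positive lags mean x lags y: feeding ``y = delay(x, d)`` peaks at +d.
    """
    xv, yv = _prep_pair(x, y, lp)
    max_n = int(round(max_lag * x.rate))
    r = _norm_xcorr(xv, yv, max_n)
    lags = np.arange(-max_n, max_n + 1) / x.rate
    ipk = int(np.argmax(np.abs(r)))
    return CrossCorrelation(lags, r, float(r[ipk]), float(lags[ipk]))


def surrogate_ci(x: TimeSeries, y: TimeSeries, max_lag: float,
                 n: int = 1000, lp: float | None = 1.0,
                 seed: int | None = None) -> np.ndarray:
    """Per-lag 95% null band for :func:`xcorr` from circular time shifts.

    Circularly shifting y preserves both autocorrelations while destroying
    the cross-channel alignment; returns (2, n_lags) with the 2.5th and
    97.5th percentiles.
    """
    if n < 100:
        raise ValueError("need at least 100 surrogates")
    rng = np.random.default_rng(seed)
    xv, yv = _prep_pair(x, y, lp)
    max_n = int(round(max_lag * x.rate))
    shifts = rng.integers(1, xv.size, size=n)
    rs = np.empty((n, 2 * max_n + 1))
    for i, s in enumerate(shifts):
        rs[i] = _norm_xcorr(xv, np.roll(yv, s), max_n)
    return np.percentile(rs, [2.5, 97.5], axis=0)


def _segment_cross_spectra(values: dict, rate: float, n_segments: int,
                           n_tapers: int = 5, nw: float = 3.0):
    """Multitaper cross-spectral matrix averaged over segments x tapers.

    Returns (freqs, {(a, b): S_ab}) for every ordered channel pair plus
    auto-spectra, and the number of averaged estimates.
    """
    names = list(values)
    n = min(v.size for v in values.values())
    seg_len = n // n_segments
    if seg_len < 8:
        raise ValueError("segments too short; provide more data or fewer segments")
    tapers = signal.windows.dpss(seg_len, nw, n_tapers)
    freqs = np.fft.rfftfreq(seg_len, 1 / rate)
    ffts = {}
    for name in names:
        v = values[name][:n_segments * seg_len].reshape(n_segments, seg_len)
        v = v - v.mean(axis=1, keepdims=True)
        # (n_segments, n_tapers, n_freqs)
        ffts[name] = np.fft.rfft(v[:, None, :] * tapers[None, :, :], axis=2)
    S = {}
    for a in names:
        for b in names:
            S[(a, b)] = (ffts[a] * np.conj(ffts[b])).mean(axis=(0, 1))
    return freqs, S, n_segments * n_tapers


def coherence(x: TimeSeries, y: TimeSeries, n_segments: int = 10,
              n_tapers: int = 5, nw: float = 3.0) -> CoherenceResult:
    """Squared coherence C2 = |S_xy|^2 / (S_x S_y).

    Requires several averaging segments: a single-window estimate is
    identically 1 and therefore rejected.
    """
    if x.rate != y.rate:
        raise ValueError("inputs must share a sampling rate")
    if n_segments * n_tapers < 2:
        raise ValueError("a single spectral estimate gives C2 == 1; average "
                         "over more segments/tapers")
    freqs, S, n_est = _segment_cross_spectra(
        {"x": x.values, "y": y.values}, x.rate, n_segments, n_tapers, nw)
    sx = S[("x", "x")].real
    sy = S[("y", "y")].real
    with np.errstate(invalid="ignore", divide="ignore"):
        c2 = np.abs(S[("x", "y")])**2 / (sx * sy)
    c2 = _mask_low_power(c2, sx, sy)
    return CoherenceResult(freqs, c2, n_estimates=n_est,
                           spectra={"S_x": sx, "S_y": sy, "S_xy": S[("x", "y")]})


def partial_coherence(x: TimeSeries, y: TimeSeries, z: TimeSeries,
                      n_segments: int = 10, n_tapers: int = 5,
                      nw: float = 3.0) -> CoherenceResult:
    """Squared partial coherence of x and y after removing the component
    predictable from z. Frequencies where z carries essentially no power
    are masked (NaN)."""
    if not (x.rate == y.rate == z.rate):
        raise ValueError("inputs must share a sampling rate")
    freqs, S, n_est = _segment_cross_spectra(
        {"x": x.values, "y": y.values, "z": z.values}, x.rate,
        n_segments, n_tapers, nw)
    sxx, syy, szz = (S[("x", "x")].real, S[("y", "y")].real, S[("z", "z")].real)
    sxy, sxz, szy = S[("x", "y")], S[("x", "z")], S[("z", "y")]
    num = np.abs(sxy * szz - sxz * szy)**2
    den = (sxx * szz - np.abs(sxz)**2) * (syy * szz - np.abs(S[("y", "z")])**2)
    # floor the denominator: when a signal is (numerically) fully explained
    # by z both numerator and denominator vanish and PC2 -> 0, not NaN
    floor = 1e-14 * sxx * syy * szz**2
    with np.errstate(invalid="ignore", divide="ignore"):
        pc2 = num / np.maximum(den, floor)
    pc2 = _mask_low_power(pc2, sxx, syy, szz)
    with np.errstate(invalid="ignore", divide="ignore"):
        c2 = _mask_low_power(np.abs(sxy)**2 / (sxx * syy), sxx, syy)
    return CoherenceResult(freqs, c2, pc2=pc2, n_estimates=n_est,
                           spectra={"S_x": sxx, "S_y": syy, "S_z": szz,
                                    "S_xy": sxy, "S_xz": sxz, "S_yz": S[("y", "z")]})


def _mask_low_power(c2: np.ndarray, *spectra, rel: float = 1e-12) -> np.ndarray:
    out = np.array(c2, dtype=float)
    for s in spectra:
        out[s < rel * s.max()] = np.nan
    return out


def band_crosscorrelogram(lfp: TimeSeries, o2: TimeSeries, max_lag: float,
                          f_lo: float = 0.1, f_hi: float = 150.0,
                          window: float = 1.0, n_tapers: int = 9,
                          nw: float = 5.0) -> dict:
    """Cross-correlation of per-band LFP power with the oxygen trace.

    The LFP spectrogram (multitaper, ~1 Hz bands) gives one power time
    series per frequency band; each is cross-correlated against the 1 Hz
    low-passed oxygen signal. Returns band centers, lags, and the
    (band x lag) correlation matrix; a constant oxygen trace is flagged
    and yields an all-zero matrix.
    """
    from .neural import multitaper_spectrogram
    spec = multitaper_spectrogram(lfp, window=window, n_tapers=n_tapers, nw=nw)
    sel = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    freqs = spec.freqs[sel]
    power = spec.power[:, sel]
    spec_rate = 1.0 / (spec.times[1] - spec.times[0])
    # align the oxygen trace onto the spectrogram time grid
    o2_lp = bandpass(o2, 0.0, min(1.0, o2.rate / 2 * 0.9)).values if o2.rate > 2 else o2.values
    o2_on_grid = np.interp(spec.times, o2.times, o2_lp)
    max_n = int(round(max_lag * spec_rate))
    lags = np.arange(-max_n, max_n + 1) / spec_rate
    if np.ptp(o2_on_grid) <= 1e-12 * max(1.0, np.abs(o2_on_grid).max()):
        return {"freqs": freqs, "lags": lags,
                "r": np.zeros((freqs.size, lags.size)), "constant_o2": True}
    yv = o2_on_grid - o2_on_grid.mean()
    r = np.empty((freqs.size, lags.size))
    for i in range(freqs.size):
        xv = power[:, i] - power[:, i].mean()
        if xv.std() == 0:
            r[i] = 0.0
            continue
        r[i] = _norm_xcorr(xv, yv, max_n)
    return {"freqs": freqs, "lags": lags, "r": r, "constant_o2": False}


# ---------------------------------------------------------------------------
# Exact Wilcoxon signed-rank test


def _signed_rank_distribution(ranks2: np.ndarray):
    """Exact distribution of the positive-rank sum over all 2^n sign
    assignments, on ranks pre-scaled by 2 so midranks are integers.

    Full enumeration for n <= 16; for larger n the identical distribution
    is built by convolution (each rank contributes 0 or its value
    independently).
    """
    n = ranks2.size
    total = int(ranks2.sum())
    if n <= 16:
        sums = np.zeros(1, dtype=np.int64)
        for r in ranks2:
            sums = np.concatenate([sums, sums + int(r)])
        counts = np.bincount(sums, minlength=total + 1).astype(float)
    else:
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in ranks2:
            r = int(r)
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:total + 1 - r]
            counts = counts + shifted
    return counts / 2.0**n


def wilcoxon_exact(diffs, sides: str = "two") -> float:
    """Exact Wilcoxon signed-rank p value by enumeration of sign flips.

    Zero differences are dropped (the standard convention); ties in |d|
    receive midranks. Exact up to n = 25 non-zero differences. ``sides``
    is 'two' (symmetric tail doubling, capped at 1) or 'one' (probability
    of a rank sum at least as positive).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: test undefined")
    if n > 25:
        raise ValueError("exact enumeration supported up to n = 25")
    if sides not in ("one", "two"):
        raise ValueError("sides must be 'one' or 'two'")
    # midranks of |d|
    order = np.argsort(np.abs(d), kind="stable")
    ranks = np.empty(n)
    a = np.abs(d)[order]
    i = 0
    pos = 1
    while i < n:
        j = i
        while j + 1 < n and a[j + 1] == a[i]:
            j += 1
        ranks[order[i:j + 1]] = (pos + (pos + (j - i))) / 2.0
        pos += j - i + 1
        i = j + 1
    ranks2 = np.round(ranks * 2).astype(int)
    w2 = int(np.round(ranks[d > 0].sum() * 2))
    pmf = _signed_rank_distribution(ranks2)
    p_ge = pmf[w2:].sum()
    p_le = pmf[:w2 + 1].sum()
    if sides == "one":
        return float(p_ge)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))
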