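"""Reflectance-based CBV metrics and modified Beer-Lambert spectroscopy.

Multi-wavelength reflectance changes are converted to oxy-/deoxyhemoglobin
concentration changes via

    dA(lambda) = -ln(R/R0) = X(lambda) * [eps_HbO dHbO + eps_HbR dHbR]

solved per sample by least squares (exact for two wavelengths; the
three-wavelength oxygen-challenge configuration is overdetermined). The
cerebral oxygenation index is dHbO - dHbR. Also houses the event-triggered
averaging shared by all channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import TimeSeries

__all__ = ["PathlengthTable", "HemoPair", "ReflectanceStack", "delta_r",
           "beer_lambert_forward", "beer_lambert_invert", "triggered_average"]


@dataclass
class PathlengthTable:
    """Per-wavelength extinction coefficients (1/(uM*cm)) times pathlength
    factors. Loaded from an editable CSV; all entries must be positive."""

    wavelengths: np.ndarray
    eps_hbo: np.ndarray     # 1/(uM*cm)
    eps_hbr: np.ndarray
    pathlength: np.ndarray  # cm

    def __post_init__(self) -> None:
        for name in ("eps_hbo", "eps_hbr", "pathlength"):
            if (getattr(self, name) <= 0).any():
                raise ValueError(f"{name} entries must be positive")
        if np.unique(self.wavelengths).size != self.wavelengths.size:
            raise ValueError("wavelengths must be distinct")

    @classmethod
    def default(cls) -> "PathlengthTable":
        src = resources.files("neuroxkit.data") / "optical_pathlength.csv"
        with resources.as_file(src) as path:
            df = pd.read_csv(path, comment="#")
        return cls(df["wavelength_nm"].to_numpy(float),
                   df["eps_hbo"].to_numpy(float) * 1e-6,   # 1/(cm*M) -> 1/(cm*uM)
                   df["eps_hbr"].to_numpy(float) * 1e-6,
                   df["pathlength_cm"].to_numpy(float))

    def design(self, wavelengths) -> np.ndarray:
        """(n_lambda x 2) matrix mapping (dHbO, dHbR) to attenuation dA."""
        rows = []
        for wl in wavelengths:
            i = np.flatnonzero(np.isclose(self.wavelengths, wl))
            if i.size == 0:
                raise ValueError(f"no table entry for wavelength {wl} nm")
            i = i[0]
            rows.append([self.eps_hbo[i] * self.pathlength[i],
                         self.eps_hbr[i] * self.pathlength[i]])
        return np.asarray(rows)


@dataclass
class HemoPair:
    """Oxy/deoxyhemoglobin concentration changes and their index."""

    dHbO: TimeSeries
    dHbR: TimeSeries
    index: TimeSeries  # dHbO - dHbR, the cerebral oxygenation index


@dataclass
class ReflectanceStack:
    """Reflectance frames per wavelength: {wavelength_nm: time x pixel}."""

    frames: dict
    rate: float
    roi_masks: dict
    t0: float = 0.0

    def __post_init__(self) -> None:
        for wl, arr in self.frames.items():
            if (np.asarray(arr) <= 0).any():
                raise ValueError(f"non-positive reflectance at {wl} nm")


def delta_r(stack: ReflectanceStack, roi: str, baseline: tuple[float, float],
            wavelength: float | None = None) -> TimeSeries:
    """ROI-mean percentage reflectance change, dR/R0 in percent.

    ``baseline`` is a (start, stop) time interval defining R0.
    """
    if roi not in stack.roi_masks:
        raise ValueError(f"unknown ROI {roi!r}")
    mask = np.asarray(stack.roi_masks[roi])
    if mask.sum() == 0:
        raise ValueError(f"ROI {roi!r} is empty")
    if wavelength is None:
        wavelength = sorted(stack.frames)[0]
    frames = np.asarray(stack.frames[wavelength])
    mean_r = frames[:, mask.astype(bool)].mean(axis=1)
    n = mean_r.size
    i0 = int(round((baseline[0] - stack.t0) * stack.rate))
    i1 = int(round((baseline[1] - stack.t0) * stack.rate))
    if not (0 <= i0 < i1 <= n):
        raise ValueError("baseline interval outside the record")
    r0 = mean_r[i0:i1].mean()
    return TimeSeries((mean_r / r0 - 1.0) * 100.0, stack.rate, stack.t0, units="%")


def beer_lambert_forward(dhbo: np.ndarray, dhbr: np.ndarray, wavelengths,
                         table: PathlengthTable | None = None) -> dict:
    """Forward map: relative reflectance R/R0 per wavelength from known
    chromophore changes (uM). Inverse of :func:`beer_lambert_invert`."""
    table = table or PathlengthTable.default()
    A = table.design(wavelengths)
    out = {}
    for k, wl in enumerate(wavelengths):
        dA = A[k, 0] * np.asarray(dhbo) + A[k, 1] * np.asarray(dhbr)
        out[wl] = np.exp(-dA)
    return out


def beer_lambert_invert(dr: dict, rate: float, table: PathlengthTable | None = None,
                        t0: float = 0.0) -> HemoPair:
    """Invert the modified Beer-Lambert law.

    ``dr`` maps wavelength (nm) to relative reflectance R/R0 (unitless,
    positive). Attenuations dA = -ln(R/R0) are solved for (dHbO, dHbR) by
    least squares across wavelengths.
    """
    wavelengths = sorted(dr)
    if len(wavelengths) < 2:
        raise ValueError("need at least two wavelengths")
    table = table or PathlengthTable.default()
    A = table.design(wavelengths)
    cond = np.linalg.cond(A)
    if cond > 1e3:
        raise ValueError(f"extinction matrix ill-conditioned (cond {cond:.3g}) "
                         f"for wavelengths {wavelengths}")
    dA = np.stack([-np.log(np.asarray(dr[wl], dtype=float)) for wl in wavelengths])
    sol, *_ = np.linalg.lstsq(A, dA, rcond=None)
    dhbo = TimeSeries(sol[0], rate, t0, units="uM")
    dhbr = TimeSeries(sol[1], rate, t0, units="uM")
    index = TimeSeries(sol[0] - sol[1], rate, t0, units="uM")
    return HemoPair(dhbo, dhbr, index)


def triggered_average(ts: TimeSeries, events: pd.DataFrame,
                      window: tuple[float, float]) -> dict:
    """Event-aligned mean with dispersion.

    ``window`` is (pre, post) in seconds around each event onset. Events
    whose window falls outside the record are excluded and counted. Returns
    a dict with rel_times, mean, sd, sem, n, n_excluded (sd/sem are NaN and
    flagged when n == 1).
    """
    pre, post = window
    n_pre = int(round(pre * ts.rate))
    n_post = int(round(post * ts.rate))
    segs = []
    excluded = 0
    for onset in events["onset"]:
        i0 = int(round((onset - ts.t0) * ts.rate))
        if i0 - n_pre < 0 or i0 + n_post > ts.n:
            excluded += 1
            continue
        segs.append(ts.values[i0 - n_pre:i0 + n_post])
    if not segs:
        return {"rel_times": np.arange(-n_pre, n_post) / ts.rate, "mean": None,
                "sd": None, "sem": None, "n": 0, "n_excluded": excluded}
    arr = np.asarray(segs)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    if n > 1:
        sd = arr.std(axis=0, ddof=1)
        sem = sd / np.sqrt(n)
    else:
        sd = np.full(arr.shape[1], np.nan)
        sem = np.full(arr.shape[1], np.nan)
    return {"rel_times": np.arange(-n_pre, n_post) / ts.rate, "mean": mean,
            "sd": sd, "sem": sem, "n": n, "n_excluded": excluded}
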