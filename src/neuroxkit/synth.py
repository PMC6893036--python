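"""Synthetic multimodal sessions with known ground truth.

Emulates the statistical structure the analyses assume: treadmill velocity
with Poisson-arriving locomotion bouts, 1/f LFP whose gamma band is gain-
modulated by locomotion, MUA built from fast-spiking / regular-spiking
templates at state-dependent rates, tissue oxygen generated by convolving
a known response kernel with binarized locomotion plus a respiration-
coupled term, a thermocouple respiration trace (raised-cosine pulse per
breath, expiratory peak), two-wavelength reflectance produced by the
Beer-Lambert forward map of a known chromophore pair, and phosphorescence
decay records whose lifetimes follow the Stern-Volmer map of instantaneous
arterial oxygen. Identical seed and configuration give bit-identical
sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from . import behavior, kernel
from .core import BinarySeries, TimeSeries
from .hemodyn import beer_lambert_forward
from .respphase import DECAY_RATE, GATE_DISCARD, DecaySet, OximetryCalibration

__all__ = ["GroundTruth", "SyntheticSession", "SessionConfig", "default_hrf",
           "generate_session", "generate_decays", "spike_template"]


def default_hrf(rate: float = 30.0, duration: float = 15.0,
                peak_time: float = 2.5, total: float = 5.0) -> np.ndarray:
    """Gamma-shaped impulse response at the analysis rate.

    Scaled so a sustained locomotion step asymptotes to ``total`` signal
    units (sum of kernel samples = ``total``).
    """
    t = np.arange(int(duration * rate)) / rate
    shape = 3.0
    h = (t / peak_time)**(shape - 1) * np.exp(-(shape - 1) * (t / peak_time - 1))
    return h / h.sum() * total


@dataclass
class GroundTruth:
    """Everything the generator imposed, for downstream verification."""

    hrf_true: np.ndarray
    hrf_rate: float = 30.0
    gamma_gain_loco: float = 2.0
    resp_rate_rest: float = 2.5
    resp_rate_loco: float = 4.0
    resp_modulation_depth: float = 5.0
    fs_fraction: float = 0.3
    fs_ptt: float = 0.3            # ms
    rs_ptt: float = 0.7            # ms
    pao2_baseline: float = 35.0    # mmHg
    seed: int = 0
    bouts: np.ndarray | None = None           # (n, 2) onset/offset s
    delta30: BinarySeries | None = None       # binarized locomotion, 30 Hz
    pto2_clean30: np.ndarray | None = None    # noiseless convolved PtO2
    expiratory_peaks: np.ndarray | None = None
    dhbo: np.ndarray | None = None            # uM at frame rate
    dhbr: np.ndarray | None = None
    spike_times: np.ndarray | None = None
    spike_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.resp_rate_rest <= 0 or self.resp_rate_loco <= 0:
            raise ValueError("respiration rates must be positive")
        if self.resp_modulation_depth < 0:
            raise ValueError("modulation depth must be >= 0")
        if not (0 <= self.fs_fraction <= 1):
            raise ValueError("fs_fraction must lie in [0, 1]")


@dataclass
class SessionConfig:
    """Generator settings. Defaults are the study conditions emulated
    throughout the test suite."""

    duration: float = 300.0
    analog_rate: float = 1000.0
    neural_rate: float = 20000.0
    frame_rate: float = 30.0
    analysis_rate: float = 30.0
    # locomotion bout statistics
    bout_rate_per_min: float = 2.0
    bout_shape: float = 3.0          # gamma shape of bout duration
    bout_scale: float = 4.0          # gamma scale (s); mean = shape*scale
    min_gap: float = 1.0             # s added to exponential inter-bout gaps
    gait_freq: float = 1.5           # Hz, within-bout velocity oscillation
    velocity_amp: float = 5.0        # cm/s
    velocity_noise_sd: float = 0.01  # cm/s
    # neural channel
    gamma_gain_loco: float = 2.0
    lfp_amplitude: float = 1.0
    mua_noise_sd: float = 1.0
    spike_rate_rest: float = 5.0     # Hz
    spike_rate_gain: float = 2.0     # x during locomotion
    spike_amplitude: float = 10.0    # x noise SD
    fs_fraction: float = 0.3
    fs_ptt: float = 0.3              # ms
    rs_ptt: float = 0.7              # ms
    ptt_jitter_sd: float = 0.05      # ms
    # oxygen channel
    pao2_baseline: float = 35.0
    pto2_noise_sd: float = 0.5       # mmHg
    resp_coupling: float = 0.2       # mmHg sinusoid on PtO2 at resp phase
    hrf: np.ndarray | None = None    # default: default_hrf()
    # respiration
    resp_rate_rest: float = 2.5
    resp_rate_loco: float = 4.0
    resp_modulation_depth: float = 5.0
    # reflectance
    n_pixels: int = 16
    dhbo_gain: float = 20.0          # uM at sustained locomotion
    dhbr_gain: float = -10.0
    reflect_noise: float = 0.0
    # decays
    decay_rate: float = 1000.0       # records per second
    decay_samples: int = 128
    decay_amplitude: float = 1000.0
    decay_background: float = 2.0
    calib: OximetryCalibration = field(default_factory=OximetryCalibration)

    def __post_init__(self) -> None:
        if self.duration < 60:
            raise ValueError("session duration must be at least 60 s")
        for name in ("analog_rate", "neural_rate", "frame_rate", "analysis_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticSession:
    velocity: TimeSeries
    lfp: TimeSeries
    mua: TimeSeries
    pto2: TimeSeries
    thermocouple: TimeSeries
    reflect_530: np.ndarray      # time x pixel
    reflect_470: np.ndarray
    decays: DecaySet
    truth: GroundTruth
    frame_rate: float = 30.0


# --------------------------------------------------------------------------
# pieces

def _draw_bouts(cfg: SessionConfig, rng: np.random.Generator) -> np.ndarray:
    """Poisson-arriving bouts: inter-bout gap = min_gap + Exp(mean), bout
    duration ~ Gamma(shape, scale). Returns (n, 2) onset/offset seconds."""
    if cfg.bout_rate_per_min <= 0:
        return np.empty((0, 2))
    mean_gap = 60.0 / cfg.bout_rate_per_min
    bouts = []
    t = 5.0 + rng.exponential(mean_gap)
    while True:
        dur = rng.gamma(cfg.bout_shape, cfg.bout_scale)
        if t + dur > cfg.duration - 2.0:
            break
        bouts.append((t, t + dur))
        t = t + dur + cfg.min_gap + rng.exponential(mean_gap)
    return np.asarray(bouts).reshape(-1, 2)


def _velocity(cfg: SessionConfig, bouts: np.ndarray,
              rng: np.random.Generator) -> TimeSeries:
    n = int(cfg.duration * cfg.analog_rate)
    t = np.arange(n) / cfg.analog_rate
    v = rng.normal(0, cfg.velocity_noise_sd, n)
    for on, off in bouts:
        sel = (t >= on) & (t < off)
        tt = t[sel] - on
        env = np.minimum(1.0, np.minimum(tt, (off - on) - tt) / 0.25)
        v[sel] += cfg.velocity_amp * (1 - np.cos(2 * np.pi * cfg.gait_freq * tt)) * env
    return TimeSeries(v, cfg.analog_rate, units="cm/s")


def _state(times: np.ndarray, bouts: np.ndarray) -> np.ndarray:
    s = np.zeros(times.size, dtype=bool)
    for on, off in bouts:
        s |= (times >= on) & (times < off)
    return s


def _pink_noise(n: int, rng: np.random.Generator, rate: float,
                f_floor: float = 0.1) -> np.ndarray:
    w = rng.normal(0, 1, n)
    f = np.fft.rfftfreq(n, 1 / rate)
    shaping = 1.0 / np.sqrt(np.maximum(f, f_floor))
    x = np.fft.irfft(np.fft.rfft(w) * shaping, n)
    return x / x.std()


def _lfp(cfg: SessionConfig, bouts: np.ndarray, rng: np.random.Generator) -> TimeSeries:
    n = int(cfg.duration * cfg.neural_rate)
    base = _pink_noise(n, rng, cfg.neural_rate)
    band_of = lambda x: signal.sosfiltfilt(
        signal.butter(4, [40, 100], btype="band", fs=cfg.neural_rate, output="sos"), x)
    base_nb = base - band_of(base)
    band = band_of(_pink_noise(n, rng, cfg.neural_rate))
    t = np.arange(n) / cfg.neural_rate
    g = np.where(_state(t, bouts), np.sqrt(cfg.gamma_gain_loco), 1.0)
    return TimeSeries(cfg.lfp_amplitude * (base_nb + band * g),
                      cfg.neural_rate, units="a.u.")


def spike_template(ptt_ms: float, rate: float, half_ms: float = 1.5) -> np.ndarray:
    """Biphasic spike stereotype: positive peak then a trough ``ptt_ms``
    later, unit peak amplitude."""
    n = int(round(2 * half_ms * 1e-3 * rate)) + 1
    t = (np.arange(n) / rate) * 1e3 - half_ms  # ms, peak at 0
    w = np.exp(-0.5 * (t / 0.08)**2) - 0.55 * np.exp(-0.5 * ((t - ptt_ms) / 0.15)**2)
    return w / w.max()


def _mua(cfg: SessionConfig, bouts: np.ndarray, rng: np.random.Generator):
    n = int(cfg.duration * cfg.neural_rate)
    hi = min(3000.0, 0.45 * cfg.neural_rate)   # clamp for low-rate test configs
    sos = signal.butter(5, [min(300.0, hi / 2), hi], btype="band",
                        fs=cfg.neural_rate, output="sos")
    noise = signal.sosfiltfilt(sos, rng.normal(0, 1, n))
    noise *= cfg.mua_noise_sd / noise.std()
    x = noise.copy()
    # state-dependent Poisson spike train with a 2 ms refractory period
    peak_rate = cfg.spike_rate_rest * cfg.spike_rate_gain
    cand = np.sort(rng.uniform(0, cfg.duration, rng.poisson(peak_rate * cfg.duration)))
    loco = _state(cand, bouts)
    keep = rng.uniform(size=cand.size) < np.where(loco, 1.0, 1.0 / cfg.spike_rate_gain)
    times = cand[keep]
    times = times[np.concatenate(([True], np.diff(times) > 2e-3))]
    labels = np.where(rng.uniform(size=times.size) < cfg.fs_fraction, "FS", "RS")
    amp = cfg.spike_amplitude * cfg.mua_noise_sd
    for t0, lab in zip(times, labels):
        ptt = (cfg.fs_ptt if lab == "FS" else cfg.rs_ptt)
        ptt = max(0.1, ptt + rng.normal(0, cfg.ptt_jitter_sd))
        tpl = spike_template(ptt, cfg.neural_rate)
        i = int(round(t0 * cfg.neural_rate))
        j0, j1 = i - tpl.size // 2, i + tpl.size // 2 + 1
        if j0 < 0 or j1 > n:
            continue
        x[j0:j1] += amp * tpl * rng.lognormal(0, 0.05)
    return TimeSeries(x, cfg.neural_rate, units="a.u."), times, labels


def _respiration(cfg: SessionConfig, bouts: np.ndarray, rng: np.random.Generator):
    """Thermocouple trace and its expiratory-peak times.

    Breath-by-breath: each cycle's duration is set by the current state's
    rate (rest vs locomotion) with mild jitter; the waveform is one
    raised-cosine pulse per cycle whose maximum marks expiration.
    """
    peaks = []
    t = 0.3
    while t < cfg.duration - 1.0:
        rate = cfg.resp_rate_loco if _state(np.array([t]), bouts)[0] else cfg.resp_rate_rest
        peaks.append(t)
        t += (1.0 / rate) * (1 + rng.normal(0, 0.02))
    peaks = np.asarray(peaks)
    n = int(cfg.duration * cfg.analog_rate)
    tt = np.arange(n) / cfg.analog_rate
    idx = np.searchsorted(peaks, tt, side="right") - 1
    thermo = np.zeros(n)
    valid = (idx >= 0) & (idx < peaks.size - 1)
    cyc = np.diff(peaks)
    frac = np.zeros(n)
    frac[valid] = (tt[valid] - peaks[idx[valid]]) / cyc[np.minimum(idx[valid], cyc.size - 1)]
    width = 0.6
    pulse = np.where(np.abs(frac) < width / 2,
                     0.5 * (1 + np.cos(2 * np.pi * frac / width)), 0.0)
    pulse2 = np.where(np.abs(frac - 1.0) < width / 2,
                      0.5 * (1 + np.cos(2 * np.pi * (frac - 1.0) / width)), 0.0)
    thermo = np.where(valid, pulse + pulse2, 0.0)
    thermo += rng.normal(0, 0.01, n)
    return TimeSeries(thermo, cfg.analog_rate, units="a.u."), peaks


def _phase_since(times: np.ndarray, peaks: np.ndarray):
    """(time since last peak, cycle length) per sample; NaN outside cycles."""
    idx = np.searchsorted(peaks, times, side="right") - 1
    cyc = np.diff(peaks)
    phase = np.full(times.size, np.nan)
    T = np.full(times.size, np.nan)
    ok = (idx >= 0) & (idx < cyc.size)
    phase[ok] = times[ok] - peaks[idx[ok]]
    T[ok] = cyc[idx[ok]]
    return phase, T


def _pto2(cfg: SessionConfig, delta30: BinarySeries, resp_peaks: np.ndarray,
          hrf: np.ndarray, rng: np.random.Generator):
    L = kernel.build_design(delta30, hrf.size)
    clean30 = cfg.pao2_baseline + L @ np.concatenate(([0.0], hrf))
    n = int(cfg.duration * cfg.analog_rate)
    t = np.arange(n) / cfg.analog_rate
    t30 = np.arange(delta30.n) / delta30.rate
    v = np.interp(t, t30, clean30)
    phase, T = _phase_since(t, resp_peaks)
    with np.errstate(invalid="ignore"):
        mod = cfg.resp_coupling * np.sin(2 * np.pi * phase / T)
    v = v + np.where(np.isfinite(mod), mod, 0.0)
    v = v + rng.normal(0, cfg.pto2_noise_sd, n)
    return TimeSeries(v, cfg.analog_rate, units="mmHg"), clean30


def _reflectance(cfg: SessionConfig, delta30: BinarySeries,
                 rng: np.random.Generator):
    n = int(cfg.duration * cfg.frame_rate)
    t = np.arange(n) / cfg.frame_rate
    t30 = np.arange(delta30.n) / delta30.rate
    # slow vascular kernel: 2 s exponential on the locomotion state
    k = np.exp(-np.arange(0, 6, 1 / delta30.rate) / 2.0)
    s30 = np.convolve(delta30.delta.astype(float), k / k.sum())[:delta30.n]
    s = np.interp(t, t30, s30)
    dhbo = cfg.dhbo_gain * s
    dhbr = cfg.dhbr_gain * s
    rr = beer_lambert_forward(dhbo, dhbr, [470.0, 530.0])
    frames = {}
    for wl in (470.0, 530.0):
        base = 1000.0 * rr[wl][:, None] * np.ones(cfg.n_pixels)
        if cfg.reflect_noise > 0:
            base = base * (1 + rng.normal(0, cfg.reflect_noise, base.shape))
        frames[wl] = base
    return frames[530.0], frames[470.0], dhbo, dhbr


def generate_decays(pao2_trace: TimeSeries, resp_peaks: np.ndarray,
                    modulation_depth: float, calib: OximetryCalibration,
                    seed: int, rate: float = 1000.0, n_samples: int = 128,
                    amplitude: float = 1000.0, background: float = 2.0,
                    shot_noise: bool = True) -> DecaySet:
    """Phosphorescence decay records over the span of ``pao2_trace``.

    Instantaneous PaO2 = trace + (depth/2) * sin(2*pi*phase/cycle); each
    record is A * exp(-t/tau(PaO2)) + background with Poisson shot noise
    (exact expectation when ``shot_noise`` is False). Timestamps uniformly
    cover the trace.
    """
    resp_peaks = np.asarray(resp_peaks, dtype=float)
    if modulation_depth != 0 and resp_peaks.size == 0:
        raise ValueError("respiration-phase modulation requires expiratory peaks")
    rng = np.random.default_rng(seed)
    n_rec = int(pao2_trace.duration * rate)
    ts = pao2_trace.t0 + (np.arange(n_rec) + 0.5) / rate
    base = np.interp(ts, pao2_trace.times, pao2_trace.values)
    if modulation_depth != 0:
        phase, T = _phase_since(ts, resp_peaks)
        with np.errstate(invalid="ignore"):
            mod = (modulation_depth / 2) * np.sin(2 * np.pi * phase / T)
        base = base + np.where(np.isfinite(mod), mod, 0.0)
    tau = calib.po2_to_tau(np.maximum(base, 0.0))          # us
    t_us = (np.arange(n_samples) / DECAY_RATE) * 1e6
    expected = amplitude * np.exp(-t_us[None, :] / tau[:, None]) + background
    samples = rng.poisson(expected).astype(float) if shot_noise else expected
    return DecaySet(samples, ts, DECAY_RATE, GATE_DISCARD)


def generate_session(config: SessionConfig | None = None, seed: int = 0) -> SyntheticSession:
    """Generate a complete multimodal session; identical (config, seed)
    pairs give bit-identical output."""
    cfg = config or SessionConfig()
    rng = np.random.default_rng(seed)
    bouts = _draw_bouts(cfg, rng)
    velocity = _velocity(cfg, bouts, rng)
    delta = behavior.binarize_locomotion(velocity)
    delta30 = behavior.resample_binary(delta, cfg.analysis_rate)
    lfp = _lfp(cfg, bouts, rng)
    mua, spike_times, spike_labels = _mua(cfg, bouts, rng)
    thermo, resp_peaks = _respiration(cfg, bouts, rng)
    hrf = cfg.hrf if cfg.hrf is not None else default_hrf(cfg.analysis_rate)
    pto2, clean30 = _pto2(cfg, delta30, resp_peaks, hrf, rng)
    r530, r470, dhbo, dhbr = _reflectance(cfg, delta30, rng)
    decays = generate_decays(
        TimeSeries(np.full(int(cfg.duration), cfg.pao2_baseline), 1.0, units="mmHg"),
        resp_peaks, cfg.resp_modulation_depth, cfg.calib,
        seed=int(rng.integers(2**31 - 1)), rate=cfg.decay_rate,
        n_samples=cfg.decay_samples, amplitude=cfg.decay_amplitude,
        background=cfg.decay_background)
    truth = GroundTruth(
        hrf_true=hrf, hrf_rate=cfg.analysis_rate,
        gamma_gain_loco=cfg.gamma_gain_loco, resp_rate_rest=cfg.resp_rate_rest,
        resp_rate_loco=cfg.resp_rate_loco,
        resp_modulation_depth=cfg.resp_modulation_depth,
        fs_fraction=cfg.fs_fraction, fs_ptt=cfg.fs_ptt, rs_ptt=cfg.rs_ptt,
        pao2_baseline=cfg.pao2_baseline, seed=seed, bouts=bouts,
        delta30=delta30, pto2_clean30=clean30, expiratory_peaks=resp_peaks,
        dhbo=dhbo, dhbr=dhbr, spike_times=spike_times, spike_labels=spike_labels)
    return SyntheticSession(velocity, lfp, mua, pto2, thermo, r530, r470,
                            decays, truth, frame_rate=cfg.frame_rate)
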