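"""Workflow orchestration: generate -> preprocess -> analyze -> model.

A run is described by a config dict (usually loaded from YAML): a seed
(mandatory for stochastic stages), a stage list in dependency order, and
per-stage parameter overrides. Every run writes a manifest recording the
parameters, seed, package version and SHA-256 of each product, so two runs
with equal config and seed produce byte-identical deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import (__version__, behavior, coupling, io, kernel, neural, preproc,
               respphase, synth, transport)
from .core import TimeSeries

__all__ = ["run_pipeline", "validate_session", "STAGES"]

log = logging.getLogger("neuroxkit")

STAGES = ("generate", "binarize", "preprocess", "kernel", "coupling",
          "respphase", "o2model")

_DEPS = {
    "binarize": {"generate"},
    "preprocess": {"generate"},
    "kernel": {"binarize", "preprocess"},
    "coupling": {"preprocess"},
    "respphase": {"generate"},
    "o2model": set(),
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_session(path) -> dict:
    """Schema/sanity report for a session container."""
    report = {"path": str(path), "valid": True, "violations": []}
    try:
        import h5py
        with h5py.File(path, "r") as f:
            for name, g in f.items():
                if "data" not in g:
                    report["violations"].append(f"{name}: missing data")
                    continue
                if name == "decays":
                    continue
                rate = float(g.attrs.get("rate", 0.0))
                if rate <= 0:
                    report["violations"].append(f"{name}: non-positive rate")
                data = np.asarray(g["data"])
                if data.size == 0:
                    report["violations"].append(f"{name}: empty channel")
                elif not np.isfinite(data).all():
                    report["violations"].append(f"{name}: non-finite samples")
    except OSError as exc:
        raise OSError(f"unreadable session container {path}: {exc}") from exc
    report["valid"] = not report["violations"]
    return report


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured stages and return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    done: set = set()
    for st in stages:
        missing = _DEPS.get(st, set()) - done
        if missing:
            raise ValueError(f"stage {st!r} requires {sorted(missing)} first")
        done.add(st)
    if "seed" not in config:
        raise ValueError("config must set an explicit seed")
    seed = int(config["seed"])
    params = config.get("params", {})
    manifest = {"seed": seed, "stages": stages, "version": __version__,
                "products": {}}
    ctx: dict = {}

    for st in stages:
        log.info("stage %s", st)
        opts = params.get(st, {})
        if st == "generate":
            cfg = synth.SessionConfig(**opts)
            ctx["session"] = synth.generate_session(cfg, seed=seed)
            path = outdir / "session.h5"
            s = ctx["session"]
            io.write_session(path, {
                "velocity": s.velocity, "lfp": s.lfp, "mua": s.mua,
                "pto2": s.pto2, "thermocouple": s.thermocouple},
                decays=s.decays.samples, decay_timestamps=s.decays.timestamps,
                decay_rate=s.decays.rate,
                truth={"seed": seed, "pao2_baseline": s.truth.pao2_baseline,
                       "resp_modulation_depth": s.truth.resp_modulation_depth})
            manifest["products"]["session"] = str(path)
        elif st == "binarize":
            s = ctx["session"]
            delta = behavior.binarize_locomotion(s.velocity, **opts)
            ctx["delta"] = delta
            ctx["delta30"] = behavior.resample_binary(delta, 30.0)
            events = behavior.segment_events(delta)
            path = outdir / "events.csv"
            io.events_to_csv(events, path)
            manifest["products"]["events"] = str(path)
        elif st == "preprocess":
            s = ctx["session"]
            ctx["pto2_30"] = preproc.lowpass_downsample(s.pto2, 1.0, 5, 30.0)
            path = outdir / "pto2_30hz.csv"
            io.timeseries_to_csv(ctx["pto2_30"], path)
            manifest["products"]["pto2_30hz"] = str(path)
        elif st == "kernel":
            k = int(opts.get("k", 450))
            delta30 = ctx["delta30"]
            n = min(delta30.n, ctx["pto2_30"].n)
            L = kernel.build_design(
                behavior.BinarySeries(delta30.delta[:n], delta30.rate), k)
            V = TimeSeries(ctx["pto2_30"].values[:n], 30.0, units="mmHg")
            kern = kernel.deconvolve(V, L)
            ctx["kernel"] = kern
            path = outdir / "kernel.csv"
            io.timeseries_to_csv(TimeSeries(kern.values, 30.0), path)
            (outdir / "kernel_metrics.json").write_text(json.dumps(
                {**kern.metrics, "intercept": kern.intercept}, indent=2))
            manifest["products"]["kernel"] = str(path)
        elif st == "coupling":
            s = ctx["session"]
            lfp1k = preproc.lowpass_downsample(s.lfp, 300.0, 5, 1000.0)
            sp = neural.multitaper_spectrogram(lfp1k, window=1.0, n_tapers=9, nw=5.0)
            gp = neural.gamma_power(sp)
            o2 = ctx["pto2_30"]
            gp2 = preproc.lowpass_downsample(gp, 0.9, 5, 2.0)
            o22 = preproc.lowpass_downsample(o2, 0.9, 5, 2.0)
            m = min(gp2.n, o22.n)
            xc = coupling.xcorr(TimeSeries(gp2.values[:m], 2.0),
                                TimeSeries(o22.values[:m], 2.0), max_lag=10.0,
                                lp=None)
            path = outdir / "xcorr.csv"
            io.timeseries_to_csv(TimeSeries(xc.r, 2.0, t0=xc.lags[0]), path)
            manifest["products"]["xcorr"] = str(path)
        elif st == "respphase":
            s = ctx["session"]
            thermo = preproc.bandpass(s.thermocouple, 0.0, 30.0)
            resp = respphase.detect_expiratory_peaks(thermo)
            calib = respphase.OximetryCalibration()
            prof = respphase.phase_align(s.decays, resp, calib)
            path = outdir / "cycle_profile.csv"
            import pandas as pd
            pd.DataFrame({"bin_time": prof.bin_times, "pao2": prof.pao2,
                          "count": prof.counts,
                          "smoothed": prof.smoothed if prof.smoothed is not None
                          else np.full_like(prof.pao2, np.nan)}).to_csv(path, index=False)
            manifest["products"]["cycle_profile"] = str(path)
        elif st == "o2model":
            mp = transport.ModelParams(**opts.get("params", {}))
            sc_name = opts.get("scenario", "FLHL")
            sc = (transport.flhl_scenario(mp) if sc_name == "FLHL"
                  else transport.fc_scenario(mp) if sc_name == "FC"
                  else transport.blockade_scenario(mp))
            res = transport.simulate(mp, sc, t_end=float(opts.get("t_end", 30.0)),
                                     dt=float(opts.get("dt", 0.02)))
            path = outdir / "o2model.csv"
            import pandas as pd
            pd.DataFrame({"time": res["times"], "pao2": res["pao2_probe"],
                          "pto2": res["pto2_probe"],
                          "mean_tissue": res["mean_tissue_po2"]}).to_csv(path, index=False)
            manifest["products"]["o2model"] = str(path)

    manifest["hashes"] = {k: _sha256(Path(v)) for k, v in manifest["products"].items()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
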