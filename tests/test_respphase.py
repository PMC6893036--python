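"""Respiration detection and phase-resolved arterial oximetry."""

import numpy as np
import pytest

from neuroxkit import preproc, respphase, synth
from neuroxkit.core import TimeSeries

CALIB = respphase.OximetryCalibration()


class TestExpiratoryPeaks:
    def test_sinusoid_peak_spacing_and_rate(self):
        t = np.arange(0, 20, 1 / 1000)
        thermo = TimeSeries(np.sin(2 * np.pi * 2.5 * t), 1000.0)
        resp = respphase.detect_expiratory_peaks(thermo)
        spacing = np.diff(resp.expiratory_peaks)
        assert np.abs(spacing - 0.4).max() < 0.01
        assert resp.rate.values.mean() == pytest.approx(2.5, abs=0.05)

    def test_rate_modulated_train_tracked(self, resp_session):
        thermo = preproc.bandpass(resp_session.thermocouple, 0.0, 30.0)
        resp = respphase.detect_expiratory_peaks(thermo)
        true_peaks = resp_session.truth.expiratory_peaks
        # peaks within the record should match the generator's within 20 ms
        det = resp.expiratory_peaks
        matched = [np.abs(det - tp).min() for tp in true_peaks[2:-2]]
        assert np.median(matched) < 0.02
        assert resp.rate.values.mean() == pytest.approx(
            resp_session.truth.resp_rate_rest, rel=0.05)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            respphase.detect_expiratory_peaks(TimeSeries(np.ones(5000), 1000.0))


class TestRegularityFilter:
    def _rate(self, values):
        return TimeSeries(np.asarray(values, dtype=float), 10.0)

    def test_constant_rate_accepted(self):
        ev = respphase.regularity_filter(self._rate(np.full(300, 2.5)))
        assert len(ev) == 3   # three 10 s epochs

    def test_high_sd_rejected(self, rng):
        vals = np.clip(2.5 + rng.normal(0, 0.85, 300), 0.3, 4.9)
        assert np.std(vals[:100]) > 0.6
        ev = respphase.regularity_filter(self._rate(vals))
        assert len(ev) == 0

    def test_moderate_sd_ratio_accepted(self, rng):
        # SD 0.5 -> ratio 5 > 4: accepted
        vals = 2.5 + 0.5 * np.sin(np.arange(300))
        ev = respphase.regularity_filter(self._rate(vals))
        assert len(ev) >= 1

    def test_rate_ceiling_enforced(self):
        vals = np.full(300, 2.5)
        vals[50] = 6.0   # one breath above the 5 Hz ceiling
        ev = respphase.regularity_filter(self._rate(vals))
        assert len(ev) == 2


class TestLifetimeFits:
    def test_tau0_maps_to_zero_oxygen(self):
        assert CALIB.tau_to_po2(CALIB.tau0) == pytest.approx(0.0)

    def test_po2_strictly_decreasing_in_lifetime(self):
        taus = np.linspace(5.0, CALIB.tau0, 50)
        po2 = CALIB.tau_to_po2(taus)
        assert (np.diff(po2) < 0).all()

    def test_grouped_fit_unbiased_under_shot_noise(self):
        tr = TimeSeries(np.full(40, 35.0), 1.0)
        estimates = []
        for seed in range(30):
            ds = synth.generate_decays(tr, np.array([]), 0.0, CALIB, seed=seed,
                                       rate=100.0)
            estimates.append(respphase.lifetime_to_po2(ds, CALIB, group=3000).values[0])
        est = np.asarray(estimates)
        sem = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - 35.0) < 2 * sem + 0.05

    def test_too_few_decays_rejected(self):
        tr = TimeSeries(np.full(5, 35.0), 1.0)
        ds = synth.generate_decays(tr, np.array([]), 0.0, CALIB, seed=0, rate=100.0)
        with pytest.raises(ValueError):
            respphase.lifetime_to_po2(ds, CALIB, group=3000)

    def test_per_decay_estimates_track_grouped(self):
        tr = TimeSeries(np.full(40, 35.0), 1.0)
        ds = synth.generate_decays(tr, np.array([]), 0.0, CALIB, seed=3, rate=100.0)
        tau = respphase.fit_lifetimes_loglinear(ds)
        po2 = CALIB.tau_to_po2(tau[np.isfinite(tau)])
        assert po2.mean() == pytest.approx(35.0, abs=2.0)


class TestBinomialSmooth:
    def test_constant_unchanged(self):
        y = respphase.binomial_smooth(np.full(20, 7.0))
        assert np.allclose(y, 7.0)

    def test_impulse_gives_binomial_coefficients(self):
        from math import comb
        x = np.zeros(20)
        x[10] = 1.0
        y = respphase.binomial_smooth(x, reps=5)
        expected = np.zeros(20)
        for k in range(-5, 6):
            expected[10 + k] = comb(10, 5 + k) / 2**10
        assert np.allclose(y, expected)

    def test_sinusoid_attenuation_factor(self):
        n = 20
        phase = 2 * np.pi * np.arange(n) / n
        y = respphase.binomial_smooth(np.sin(phase), reps=5)
        att = np.cos(np.pi / n) ** 10
        assert np.allclose(y, att * np.sin(phase), atol=1e-12)


class TestPhaseAlign:
    def test_bin_count_from_cycle(self, resp_session):
        thermo = preproc.bandpass(resp_session.thermocouple, 0.0, 30.0)
        resp = respphase.detect_expiratory_peaks(thermo)
        prof = respphase.phase_align(resp_session.decays, resp, CALIB)
        # 2.5 Hz cycle at 20 ms bins -> 20 bins
        assert prof.bin_times.size == 20
        assert prof.counts.sum() > 0

    def test_modulation_depth_recovered(self):
        """Imposed 5 mmHg swing recovered by Tmax - Tmin within 1 mmHg
        (averaged over recordings)."""
        depths = []
        for seed in range(6):
            cfg = synth.SessionConfig(duration=60.0, neural_rate=2000.0,
                                      bout_rate_per_min=0.0,
                                      resp_modulation_depth=5.0,
                                      decay_rate=1000.0)
            s = synth.generate_session(cfg, seed=100 + seed)
            resp = respphase.detect_expiratory_peaks(
                preproc.bandpass(s.thermocouple, 0.0, 30.0))
            prof = respphase.phase_align(s.decays, resp, CALIB)
            depths.append(prof.pao2_max - prof.pao2_min)
        assert np.mean(depths) == pytest.approx(5.0, abs=1.0)

    def test_counts_conserved(self, resp_session):
        thermo = preproc.bandpass(resp_session.thermocouple, 0.0, 30.0)
        resp = respphase.detect_expiratory_peaks(thermo)
        prof = respphase.phase_align(resp_session.decays, resp, CALIB)
        phase, kept, cycle = respphase.assign_phase(
            resp_session.decays.timestamps, resp.expiratory_peaks)
        in_bins = (phase / 0.02).astype(int) < prof.bin_times.size
        assert prof.counts.sum() == in_bins.sum()


class TestTminTmax:
    def _profile(self, pao2, bin_s=0.02):
        n = len(pao2)
        return respphase.CycleProfile(
            bin_times=(np.arange(n) + 0.5) * bin_s, pao2=np.asarray(pao2, float),
            counts=np.full(n, 100), smoothed=respphase.binomial_smooth(pao2))

    def test_sinusoid_extremes_half_cycle_apart(self):
        n = 20
        pao2 = 35 + 2.5 * np.sin(2 * np.pi * np.arange(n) / n)
        prof = self._profile(pao2)
        tmin, tmax, lo, hi = respphase.tmin_tmax(prof)
        sep = abs(tmax - tmin)
        sep = min(sep, n * 0.02 - sep)   # circular distance
        assert sep == pytest.approx(0.2, abs=0.021)
        assert hi > lo

    def test_circular_ramp_extremes_adjacent(self):
        pao2 = 30 + np.arange(20) * 0.5
        prof = self._profile(pao2)
        tmin, tmax, lo, hi = respphase.tmin_tmax(prof)
        # monotone ramp: extremes sit near the wrap point on either side
        # (circular smoothing spreads the discontinuity over a few bins)
        assert tmin < 0.1 and tmax > 0.3
        assert hi > lo

    def test_flat_profile_flagged(self):
        with pytest.raises(ValueError):
            respphase.tmin_tmax(self._profile(np.full(20, 35.0)))


class TestRespirationLockedTest:
    def _per_decay(self, session):
        resp = respphase.detect_expiratory_peaks(
            preproc.bandpass(session.thermocouple, 0.0, 30.0))
        tau = respphase.fit_lifetimes_loglinear(session.decays)
        pao2 = CALIB.tau_to_po2(tau)
        phase, kept, cycle = respphase.assign_phase(
            session.decays.timestamps, resp.expiratory_peaks)
        return pao2[kept], phase, cycle

    def test_modulated_session_significant(self, resp_session):
        pao2, phase, cycle = self._per_decay(resp_session)
        res = respphase.respiration_locked_test(pao2, phase, cycle,
                                                n_surrogates=2000, seed=1)
        assert res["significant"]
        assert res["peak_freq"] == pytest.approx(2.5, abs=0.3)

    def test_surrogate_count_convergence(self, resp_session):
        pao2, phase, cycle = self._per_decay(resp_session)
        r1 = respphase.respiration_locked_test(pao2, phase, cycle,
                                               n_surrogates=1000, seed=2)
        r2 = respphase.respiration_locked_test(pao2, phase, cycle,
                                               n_surrogates=4000, seed=3)
        assert r1["significant"] == r2["significant"]

    def test_phase_randomization_variant(self, resp_session):
        pao2, phase, cycle = self._per_decay(resp_session)
        res = respphase.respiration_locked_test(pao2, phase, cycle,
                                                n_surrogates=1000, seed=4,
                                                method="phase")
        assert res["significant"]

    def test_bad_resp_freq_rejected(self, resp_session):
        pao2, phase, cycle = self._per_decay(resp_session)
        with pytest.raises(ValueError):
            respphase.respiration_locked_test(pao2, phase, cycle,
                                              resp_freq=100.0,
                                              n_surrogates=1000, seed=0)
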