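"""Cross-correlation, coherence, partial coherence, exact Wilcoxon."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sg
from scipy.stats import wilcoxon as scipy_wilcoxon

from neuroxkit import coupling
from neuroxkit.core import TimeSeries


class TestXcorr:
    def test_self_correlation_peaks_at_zero(self, rng):
        x = TimeSeries(rng.normal(0, 1, 5000), 30.0)
        xc = coupling.xcorr(x, x, max_lag=5.0)
        assert xc.peak_lag == 0.0
        assert xc.peak_r == pytest.approx(1.0, abs=1e-9)

    def test_delayed_copy_peaks_at_positive_delay(self, rng):
        rate = 30.0
        x = rng.normal(0, 1, 20000)
        y = np.roll(x, int(2.0 * rate))      # y = x delayed by 2 s
        xc = coupling.xcorr(TimeSeries(x, rate), TimeSeries(y, rate), max_lag=5.0)
        assert xc.peak_lag == pytest.approx(2.0, abs=1 / rate)
        # brute-force shift-and-dot oracle at the peak lag
        xf = sg.sosfiltfilt(sg.butter(5, 1.0, fs=rate, output="sos"), x)
        yf = sg.sosfiltfilt(sg.butter(5, 1.0, fs=rate, output="sos"), y)
        xf -= xf.mean(); yf -= yf.mean()
        k = int(2.0 * rate)
        brute = np.dot(xf[:-k], yf[k:]) / np.sqrt((xf**2).sum() * (yf**2).sum())
        i = int(np.argmin(np.abs(xc.lags - 2.0)))
        assert xc.r[i] == pytest.approx(brute, abs=1e-3)

    def test_independent_noise_near_zero(self, rng):
        n = 10000
        x = TimeSeries(rng.normal(0, 1, n), 30.0)
        y = TimeSeries(rng.normal(0, 1, n), 30.0)
        xc = coupling.xcorr(x, y, max_lag=3.0, lp=None)
        assert np.abs(xc.r).max() < 3 / np.sqrt(n)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            coupling.xcorr(TimeSeries(np.ones(100), 10.0),
                           TimeSeries(np.ones(100), 10.0), 1.0, lp=None)


class TestSurrogateCI:
    def test_null_calibration(self, rng):
        """Independent signals exceed the 95% band at roughly 5% of lags."""
        rate, n = 10.0, 3000
        frac = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            x = TimeSeries(r.normal(0, 1, n), rate)
            y = TimeSeries(r.normal(0, 1, n), rate)
            xc = coupling.xcorr(x, y, max_lag=5.0, lp=1.0)
            band = coupling.surrogate_ci(x, y, max_lag=5.0, n=200, lp=1.0,
                                         seed=seed)
            out = (xc.r < band[0]) | (xc.r > band[1])
            frac.append(out.mean())
        assert np.mean(frac) == pytest.approx(0.05, abs=0.03)

    def test_coupled_pair_exceeds_band(self, rng):
        rate, n = 10.0, 4000
        x = rng.normal(0, 1, n)
        y = 0.8 * x + 0.3 * rng.normal(0, 1, n)
        tx, ty = TimeSeries(x, rate), TimeSeries(y, rate)
        xc = coupling.xcorr(tx, ty, max_lag=5.0)
        band = coupling.surrogate_ci(tx, ty, max_lag=5.0, n=300, seed=0)
        i = int(np.argmax(np.abs(xc.r)))
        assert xc.r[i] > band[1][i]

    def test_too_few_surrogates_rejected(self, rng):
        x = TimeSeries(rng.normal(0, 1, 500), 10.0)
        with pytest.raises(ValueError):
            coupling.surrogate_ci(x, x, 1.0, n=50)


class TestCoherence:
    def test_identical_signals_unit_coherence(self, rng):
        x = TimeSeries(rng.normal(0, 1, 6000), 30.0)
        c = coupling.coherence(x, x)
        assert np.nanmin(c.c2) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_bias(self, rng):
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = TimeSeries(r.normal(0, 1, 12000), 30.0)
            y = TimeSeries(r.normal(0, 1, 12000), 30.0)
            c = coupling.coherence(x, y)
            vals.append(np.nanmean(c.c2))
        # known estimator bias ~ 1/(number of averaged estimates)
        expected = 1.0 / c.n_estimates
        assert np.mean(vals) == pytest.approx(expected, rel=0.4)

    def test_filtered_signal_coherent_in_band(self, rng):
        rate = 100.0
        x = rng.normal(0, 1, 30000)
        sos = sg.butter(4, [5, 15], btype="band", fs=rate, output="sos")
        y = sg.sosfiltfilt(sos, x) + 0.05 * rng.normal(0, 1, 30000)
        c = coupling.coherence(TimeSeries(x, rate), TimeSeries(y, rate))
        inband = c.c2[(c.freqs > 7) & (c.freqs < 13)]
        outband = c.c2[(c.freqs > 30) & (c.freqs < 45)]
        assert np.nanmean(inband) > 0.9
        assert np.nanmean(outband) < 0.2

    def test_single_estimate_rejected(self, rng):
        x = TimeSeries(rng.normal(0, 1, 1000), 30.0)
        with pytest.raises(ValueError):
            coupling.coherence(x, x, n_segments=1, n_tapers=1)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(0, 10000))
    def test_bounded_on_random_inputs(self, seed):
        r = np.random.default_rng(seed)
        x = TimeSeries(r.normal(0, 1, 3000), 30.0)
        y = TimeSeries(np.cumsum(r.normal(0, 1, 3000)), 30.0)
        c = coupling.coherence(x, y)
        ok = np.isfinite(c.c2)
        assert (c.c2[ok] >= 0).all() and (c.c2[ok] <= 1 + 1e-12).all()


class TestPartialCoherence:
    def test_independent_conditioner_leaves_coherence(self, rng):
        x = rng.normal(0, 1, 12000)
        y = 0.7 * x + 0.7 * rng.normal(0, 1, 12000)
        z = rng.normal(0, 1, 12000)
        pc = coupling.partial_coherence(TimeSeries(x, 30.0), TimeSeries(y, 30.0),
                                        TimeSeries(z, 30.0))
        assert np.nanmean(np.abs(pc.pc2 - pc.c2)) < 0.05

    def test_common_input_removed(self, rng):
        z = rng.normal(0, 1, 12000)
        x = z + 0.3 * rng.normal(0, 1, 12000)
        y = z + 0.3 * rng.normal(0, 1, 12000)
        pc = coupling.partial_coherence(TimeSeries(x, 30.0), TimeSeries(y, 30.0),
                                        TimeSeries(z, 30.0))
        assert np.nanmean(pc.c2) > 0.7
        assert np.nanmean(pc.pc2) < 0.2 * np.nanmean(pc.c2)

    def test_total_removal_when_x_equals_z(self, rng):
        z = rng.normal(0, 1, 9000)
        y = z + 0.5 * rng.normal(0, 1, 9000)
        pc = coupling.partial_coherence(TimeSeries(z, 30.0), TimeSeries(y, 30.0),
                                        TimeSeries(z, 30.0))
        assert np.nanmax(pc.pc2) < 1e-6


class TestBandCrosscorrelogram:
    def test_gamma_coupled_ridge(self, light_session):
        """Oxygen generated from locomotion shows a positive ridge in the
        gamma rows, where the generator put the locomotion gain."""
        from neuroxkit import preproc
        o2 = preproc.lowpass_downsample(light_session.pto2, 1.0, 5, 30.0)
        out = coupling.band_crosscorrelogram(light_session.lfp, o2, max_lag=8.0,
                                             f_hi=150.0)
        gamma_rows = (out["freqs"] >= 40) & (out["freqs"] <= 100)
        low_rows = (out["freqs"] >= 110) & (out["freqs"] <= 150)
        assert out["r"][gamma_rows].max() > 0.2
        assert out["r"][gamma_rows].max() > 2 * np.abs(out["r"][low_rows]).max()

    def test_constant_oxygen_flagged(self, light_session):
        o2 = TimeSeries(np.full(3000, 30.0), 30.0)
        out = coupling.band_crosscorrelogram(light_session.lfp, o2, max_lag=5.0)
        assert out["constant_o2"]
        assert not out["r"].any()


class TestWilcoxonExact:
    def test_all_positive_small_samples(self):
        # n = 6 and n = 9, all-positive differences, two-sided
        assert coupling.wilcoxon_exact(np.ones(6)) == pytest.approx(0.03125)
        assert coupling.wilcoxon_exact(np.arange(1, 10)) == pytest.approx(
            0.00390625)

    def test_balanced_symmetric_is_one(self):
        d = np.array([1.0, 2.0, 3.0, -1.0, -2.0, -3.0])
        assert coupling.wilcoxon_exact(d) == pytest.approx(1.0)

    def test_matches_scipy_exact(self, rng):
        for _ in range(30):
            n = rng.integers(5, 13)
            d = rng.normal(0, 1, n)
            d = d[d != 0]
            if (np.abs(np.abs(d)[:, None] - np.abs(d)) < 1e-12).sum() > len(d):
                continue  # scipy's exact mode assumes no ties
            p_ours = coupling.wilcoxon_exact(d)
            p_scipy = scipy_wilcoxon(d, mode="exact").pvalue
            assert p_ours == pytest.approx(p_scipy, abs=1e-12)

    def test_enumeration_matches_convolution(self, rng):
        """The n <= 16 bit-enumeration and the large-n convolution build the
        same exact distribution (checked on overlapping n with ties)."""
        for _ in range(20):
            n = int(rng.integers(3, 13))
            d = np.round(rng.normal(0, 1, n), 1)
            d = d[d != 0]
            if d.size == 0:
                continue
            p_fast = coupling.wilcoxon_exact(d)
            p_brute = _bruteforce_wilcoxon(d)
            assert p_fast == pytest.approx(p_brute, abs=1e-12)

    def test_one_sided(self):
        assert coupling.wilcoxon_exact(np.ones(6), sides="one") == pytest.approx(
            1 / 64)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            coupling.wilcoxon_exact(np.zeros(5))

    def test_zero_differences_dropped(self):
        assert coupling.wilcoxon_exact([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.0]) == \
            pytest.approx(0.03125)


def _bruteforce_wilcoxon(d):
    """Direct 2^n enumeration oracle (midranks, two-sided)."""
    from itertools import product
    from scipy.stats import rankdata
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    ws = [np.dot(signs, ranks) for signs in product([0, 1], repeat=len(d))]
    ws = np.asarray(ws)
    p_ge = (ws >= w_obs - 1e-12).mean()
    p_le = (ws <= w_obs + 1e-12).mean()
    return min(1.0, 2 * min(p_ge, p_le))
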