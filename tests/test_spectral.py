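"""Multitaper spectra, coherence, and the theta-ratio statistic."""

import numpy as np
import pytest

from cerecoh import spectral
from cerecoh.config import AnalysisConfig
from cerecoh.core import ContinuousSignal, EpochSet

from conftest import white_pair

FS = 2000.0


def _sig(x):
    return ContinuousSignal(x, fs=FS)


class TestDPSS:
    @pytest.mark.parametrize("nw", [2.0, 3.0, 4.0])
    def test_orthonormality(self, nw):
        t = spectral.dpss_tapers(1000, nw)
        g = t @ t.T
        np.testing.assert_allclose(g, np.eye(t.shape[0]), atol=1e-8)

    def test_k_rule(self):
        assert spectral.dpss_tapers(500, 2.0).shape[0] == 3

    def test_nw_below_one_rejected(self):
        with pytest.raises(ValueError):
            spectral.dpss_tapers(500, 0.5)

    def test_first_taper_concentration_beats_random(self):
        n, nw = 1000, 2.0
        tapers = spectral.dpss_tapers(n, nw)
        w = nw / n

        def concentration(v):
            f = np.fft.rfftfreq(8 * n)
            p = np.abs(np.fft.rfft(v, 8 * n)) ** 2
            return p[f <= w].sum() / p.sum()

        rng = np.random.default_rng(0)
        v = rng.standard_normal(n)
        v /= np.linalg.norm(v)
        assert concentration(tapers[0]) > concentration(v)


class TestPSD:
    def test_sinusoid_peak_location(self, config):
        t = np.arange(int(20 * FS)) / FS
        sig = _sig(np.sin(2 * np.pi * 8.0 * t))
        est = spectral.multitaper_psd(sig, EpochSet([[0, 20.0]]), config)
        f_peak = est.freqs[np.argmax(est.power_db)]
        df = est.freqs[1] - est.freqs[0]
        assert abs(f_peak - 8.0) <= df + 1e-9

    def test_white_noise_level(self, config):
        # Parseval-based level oracle: one-sided density sigma^2 / Nyquist
        rng = np.random.default_rng(1)
        sigma = 2.0
        sig = _sig(sigma * rng.standard_normal(int(100 * FS)))
        est = spectral.multitaper_psd(sig, EpochSet([[0, 100.0]]), config)
        level = est.power_linear[5:-5].mean()
        assert abs(level / (sigma ** 2 / (FS / 2)) - 1.0) < 0.05

    def test_parseval(self, config):
        rng = np.random.default_rng(2)
        sig = _sig(rng.standard_normal(int(50 * FS)))
        est = spectral.multitaper_psd(sig, EpochSet([[0, 50.0]]), config)
        integral = np.trapezoid(est.power_linear, est.freqs)
        assert abs(integral / sig.samples.var() - 1.0) < 0.02

    def test_scaling_law(self, config):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(10 * FS))
        eps = EpochSet([[0, 10.0]])
        a = spectral.multitaper_psd(_sig(x), eps, config)
        b = spectral.multitaper_psd(_sig(10 * x), eps, config)
        np.testing.assert_allclose(b.power_db - a.power_db, 20.0, atol=1e-6)

    def test_insufficient_windows_rejected(self, config):
        sig = _sig(np.random.default_rng(0).standard_normal(int(3 * FS)))
        with pytest.raises(ValueError, match="window"):
            spectral.multitaper_psd(sig, EpochSet([[0, 2.5]]), config)

    def test_ci_brackets_estimate(self, config):
        rng = np.random.default_rng(4)
        sig = _sig(rng.standard_normal(int(20 * FS)))
        est = spectral.multitaper_psd(sig, EpochSet([[0, 20.0]]), config)
        assert np.all(est.ci_low <= est.power_db + 1e-12)
        assert np.all(est.power_db <= est.ci_high + 1e-12)


class TestCoherence:
    def test_self_coherence_is_one(self, config):
        x, _ = white_pair(0, duration=20.0)
        coh = spectral.multitaper_coherence(x, x, EpochSet([[0, 20.0]]), config)
        np.testing.assert_allclose(coh.coherence, 1.0, atol=1e-6)

    def test_symmetry_in_channel_order(self, config):
        x, y = white_pair(5, duration=20.0)
        eps = EpochSet([[0, 20.0]])
        a = spectral.multitaper_coherence(x, y, eps, config)
        b = spectral.multitaper_coherence(y, x, eps, config)
        np.testing.assert_allclose(a.coherence, b.coherence, atol=1e-12)

    def test_bounds(self, coupled_pair, full_epochs, config):
        x, y, _ = coupled_pair
        coh = spectral.multitaper_coherence(x, y, full_epochs, config)
        assert np.all(coh.coherence >= 0.0) and np.all(coh.coherence <= 1.0)
        assert 0.0 < coh.sig_level < 1.0
        assert coh.dof == 2 * coh.n_windows * coh.n_tapers

    def test_rate_mismatch_rejected(self, config):
        x, _ = white_pair(0, duration=4.0)
        y = ContinuousSignal(x.samples, fs=1000.0)
        with pytest.raises(ValueError, match="rate"):
            spectral.multitaper_coherence(x, y, EpochSet([[0, 4.0]]), config)

    def test_band_limited_shared_signal(self, config):
        # shared theta component only: coherence elevated in 5-10 Hz band
        rng = np.random.default_rng(8)
        n = int(100 * FS)
        t = np.arange(n) / FS
        from cerecoh.simulate import theta_oscillator
        shared = theta_oscillator(n, FS, 7.0, 2.0, rng)
        x = _sig(shared + rng.standard_normal(n))
        y = _sig(shared + rng.standard_normal(n))
        coh = spectral.multitaper_coherence(x, y, EpochSet([[0, 100.0]]), config)
        m_in = (coh.freqs >= 5) & (coh.freqs <= 10)
        m_out = (coh.freqs >= 20) & (coh.freqs <= 45)
        assert coh.coherence[m_in].mean() > 0.5
        assert coh.coherence[m_out].mean() < 2 * coh.sig_level

    def test_jackknife_ci_narrows_with_windows(self, config):
        widths = []
        for dur in (20.0, 80.0):
            x, y = white_pair(9, duration=dur)
            coh = spectral.multitaper_coherence(x, y, EpochSet([[0, dur]]), config)
            widths.append(float(np.mean(coh.ci_high - coh.ci_low)))
        assert widths[1] < widths[0]


class TestThetaRatio:
    def _flat(self, value, fmax=128.0):
        f = np.arange(0, fmax + 0.5, 0.5)
        return spectral.CoherenceEstimate(f, np.full(f.size, value),
                                          np.full(f.size, value),
                                          np.full(f.size, value),
                                          0.1, 10, 3)

    def test_flat_coherence_ratio_one(self, config):
        assert spectral.theta_ratio(self._flat(0.5), config) == pytest.approx(
            1.0, abs=1e-9)

    def test_step_coherence_ratio_four(self, config):
        coh = self._flat(0.2)
        m = (coh.freqs >= 5) & (coh.freqs <= 10)
        coh.coherence[m] = 0.8
        assert spectral.theta_ratio(coh, config) == pytest.approx(4.0)

    def test_grid_must_reach_cap(self, config):
        f = np.arange(0, 30.0, 0.5)
        coh = spectral.CoherenceEstimate(f, np.full(f.size, 0.5), None, None,
                                         0.1, 10, 3)
        with pytest.raises(ValueError, match="45"):
            spectral.theta_ratio(coh, config)

    def test_coupled_pair_ratio_above_one(self, coupled_pair, full_epochs, config):
        x, y, _ = coupled_pair
        coh = spectral.multitaper_coherence(x, y, full_epochs, config)
        assert spectral.theta_ratio(coh, config) > 1.0


class TestBandPower:
    def test_flat_spectrum(self):
        f = np.arange(0, 100.0, 0.5)
        est = spectral.SpectralEstimate(f, np.full(f.size, 10.0),
                                        np.full(f.size, 1.0), None, None,
                                        10, 3, 1.0, FS)
        assert spectral.band_power(est, (5, 10)) == pytest.approx(10.0)
        one_bin = spectral.band_power(est, (20.0, 20.0))
        assert one_bin == pytest.approx(10.0)

    def test_band_outside_grid_rejected(self):
        f = np.arange(0, 50.0, 0.5)
        est = spectral.SpectralEstimate(f, np.zeros(f.size), np.ones(f.size),
                                        None, None, 10, 3, 1.0, FS)
        with pytest.raises(ValueError):
            spectral.band_power(est, (40.0, 60.0))

    def test_amplitude_doubling_adds_six_db(self, config):
        from cerecoh import simulate as sim
        ps = []
        for snr in (1.0, 2.0):
            p = sim.CoupledLFPParams(duration=60.0, snr=snr,
                                     coupling_gain=0.0, seed=12)
            x, _, _ = sim.gen_coupled_lfp(p)
            est = spectral.multitaper_psd(x, EpochSet([[0, 60.0]]), config)
            ps.append(spectral.band_power(est, (6.5, 7.5)))
        assert ps[1] - ps[0] == pytest.approx(6.0, abs=1.0)
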