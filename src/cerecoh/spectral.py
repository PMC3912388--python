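"""Multitaper power and coherence on state-segmented LFP.

Epochs are tiled into non-overlapping analysis windows (default 2 s); with a
half-bandwidth of 1 Hz this gives NW = 2 and K = 2·NW − 1 = 3 Slepian
tapers.  Spectra are averaged over all window × taper estimates pooled
across the epochs of a state, the standard multitaper practice.  Error bars
are leave-one-out jackknife estimates; the coherence significance level at
``alpha`` is the analytic null quantile sqrt(1 − alpha^(1/(n_est−1))).

Power is reported as 10·log10 of linear power in µV²/Hz with no reference
constant; relative comparisons are invariant to that choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats
from scipy.signal import windows as spwin

from .config import AnalysisConfig
from .core import ContinuousSignal, EpochSet

__all__ = ["SpectralEstimate", "CoherenceEstimate", "ThetaSummary",
           "dpss_tapers", "multitaper_psd", "multitaper_coherence",
           "theta_ratio", "band_power", "theta_summary"]


@dataclass
class SpectralEstimate:
    freqs: np.ndarray
    power_db: np.ndarray
    power_linear: np.ndarray        # µV²/Hz, one-sided
    ci_low: np.ndarray              # dB
    ci_high: np.ndarray             # dB
    n_windows: int
    n_tapers: int
    bandwidth: float
    fs: float


@dataclass
class CoherenceEstimate:
    freqs: np.ndarray
    coherence: np.ndarray           # magnitude in [0, 1]
    ci_low: np.ndarray
    ci_high: np.ndarray
    sig_level: float                # analytic null quantile at alpha
    n_windows: int
    n_tapers: int

    @property
    def dof(self) -> int:
        return 2 * self.n_windows * self.n_tapers


@dataclass
class ThetaSummary:
    theta_power_db: dict[str, float]
    theta_coherence: float
    theta_ratio: float


def dpss_tapers(window_len_samples: int, time_bandwidth: float) -> np.ndarray:
    """K = 2·NW − 1 orthonormal Slepian tapers (rows), each unit energy."""
    if time_bandwidth < 1:
        raise ValueError("time-bandwidth product NW must be >= 1")
    k = int(2 * time_bandwidth - 1)
    tapers = spwin.dpss(window_len_samples, time_bandwidth, Kmax=k)
    return np.atleast_2d(tapers)


def _epoch_windows(signal: ContinuousSignal, epochs: EpochSet,
                   win_samples: int) -> np.ndarray:
    """Tile each epoch into non-overlapping full windows; skip short epochs."""
    wins = []
    for t0, t1 in epochs:
        seg = signal.slice(t0, t1)
        n_full = seg.size // win_samples
        for i in range(n_full):
            wins.append(seg[i * win_samples:(i + 1) * win_samples])
    if not wins:
        return np.empty((0, win_samples))
    return np.asarray(wins)


def _taper_ffts(windows: np.ndarray, tapers: np.ndarray, nfft: int) -> np.ndarray:
    """(n_win, K, n_freq) complex spectra of demeaned, tapered windows."""
    demeaned = windows - windows.mean(axis=1, keepdims=True)
    return np.fft.rfft(demeaned[:, None, :] * tapers[None, :, :], n=nfft, axis=2)


def _prepare(signal: ContinuousSignal, epochs: EpochSet, cfg: AnalysisConfig):
    win = int(round(cfg.mt_window * signal.fs))
    windows = _epoch_windows(signal, epochs, win)
    if windows.shape[0] < 2:
        raise ValueError("epochs supply fewer than 2 full analysis windows")
    nw = cfg.mt_window * cfg.mt_bandwidth
    tapers = dpss_tapers(win, nw)
    nfft = 1 << int(np.ceil(np.log2(win)))
    freqs = np.fft.rfftfreq(nfft, 1.0 / signal.fs)
    return windows, tapers, nfft, freqs


def multitaper_psd(signal: ContinuousSignal, epochs: EpochSet,
                   config: AnalysisConfig | None = None) -> SpectralEstimate:
    """Multitaper power spectral density with jackknife confidence interval.

    One-sided PSD; per window-taper estimate |X(f)|²/fs (unit-energy tapers),
    doubled at interior frequencies; jackknife is leave-one-estimate-out on
    the dB scale with a Student-t interval.
    """
    cfg = config or AnalysisConfig()
    windows, tapers, nfft, freqs = _prepare(signal, epochs, cfg)
    X = _taper_ffts(windows, tapers, nfft)
    est = (np.abs(X) ** 2) / signal.fs          # (n_win, K, n_freq), two-sided
    est = est.reshape(-1, freqs.size)
    scale = np.full(freqs.size, 2.0)
    scale[0] = 1.0
    if nfft % 2 == 0:
        scale[-1] = 1.0
    est = est * scale
    mean_lin = est.mean(axis=0)
    n = est.shape[0]
    # leave-one-out jackknife on the log scale
    loo = (mean_lin[None, :] * n - est) / (n - 1)
    loo_db = 10 * np.log10(np.maximum(loo, 1e-300))
    jk_mean = loo_db.mean(axis=0)
    jk_var = (n - 1) / n * np.sum((loo_db - jk_mean) ** 2, axis=0)
    tcrit = spstats.t.ppf(1 - cfg.alpha / 2, n - 1)
    power_db = 10 * np.log10(np.maximum(mean_lin, 1e-300))
    half = tcrit * np.sqrt(jk_var)
    return SpectralEstimate(freqs, power_db, mean_lin, power_db - half,
                            power_db + half, windows.shape[0], tapers.shape[0],
                            cfg.mt_bandwidth, signal.fs)


def multitaper_coherence(x: ContinuousSignal, y: ContinuousSignal,
                         epochs: EpochSet,
                         config: AnalysisConfig | None = None) -> CoherenceEstimate:
    """Magnitude coherence from averaged cross- and auto-spectra.

    The jackknife leaves one *window* out (its tapers with it) and works on
    the arctanh-stabilized scale.  ``sig_level`` is the level an independent
    pair exceeds with probability alpha at each frequency.
    """
    cfg = config or AnalysisConfig()
    if x.fs != y.fs:
        raise ValueError("sampling-rate mismatch")
    if x.n_samples != y.n_samples or x.t_start != y.t_start:
        raise ValueError("span mismatch")
    win = int(round(cfg.mt_window * x.fs))
    wx = _epoch_windows(x, epochs, win)
    wy = _epoch_windows(y, epochs, win)
    if wx.shape[0] < 2:
        raise ValueError("epochs supply fewer than 2 full analysis windows")
    nw = cfg.mt_window * cfg.mt_bandwidth
    tapers = dpss_tapers(win, nw)
    nfft = 1 << int(np.ceil(np.log2(win)))
    freqs = np.fft.rfftfreq(nfft, 1.0 / x.fs)
    X = _taper_ffts(wx, tapers, nfft)
    Y = _taper_ffts(wy, tapers, nfft)
    sxx_w = (np.abs(X) ** 2).mean(axis=1)       # (n_win, n_freq)
    syy_w = (np.abs(Y) ** 2).mean(axis=1)
    sxy_w = (X * np.conj(Y)).mean(axis=1)
    n_win, n_tap = wx.shape[0], tapers.shape[0]

    def coh_from(sxx, syy, sxy):
        return np.abs(sxy) / np.sqrt(np.maximum(sxx * syy, 1e-300))

    coh = coh_from(sxx_w.mean(0), syy_w.mean(0), sxy_w.mean(0))
    # leave-one-window-out jackknife with arctanh variance stabilization
    loo = np.empty((n_win, freqs.size))
    for i in range(n_win):
        m = np.ones(n_win, bool)
        m[i] = False
        loo[i] = coh_from(sxx_w[m].mean(0), syy_w[m].mean(0), sxy_w[m].mean(0))
    z = np.arctanh(np.clip(loo, 0.0, 1.0 - 1e-12))
    z_mean = z.mean(axis=0)
    z_var = (n_win - 1) / n_win * np.sum((z - z_mean) ** 2, axis=0)
    zc = np.arctanh(np.clip(coh, 0.0, 1.0 - 1e-12))
    half = spstats.norm.ppf(1 - cfg.alpha / 2) * np.sqrt(z_var)
    n_est = n_win * n_tap
    sig = float(np.sqrt(1.0 - cfg.alpha ** (1.0 / (n_est - 1))))
    return CoherenceEstimate(freqs, coh, np.tanh(zc - half), np.tanh(zc + half),
                             sig, n_win, n_tap)


def theta_ratio(coh: CoherenceEstimate, config: AnalysisConfig | None = None) -> float:
    """Mean theta-band coherence over mean coherence at all other
    frequencies up to the cap (default 45 Hz); the band split on the
    computed grid is [5, 10] vs (0, 5) ∪ (10, 45]."""
    cfg = config or AnalysisConfig()
    lo, hi = cfg.theta_band
    f = coh.freqs
    if f[-1] < cfg.ratio_cap:
        raise ValueError(f"frequency grid ends at {f[-1]:.1f} Hz, "
                         f"below the {cfg.ratio_cap} Hz cap")
    in_theta = (f >= lo) & (f <= hi)
    out_theta = (f > 0) & (f <= cfg.ratio_cap) & ~in_theta
    if not in_theta.any() or not out_theta.any():
        raise ValueError("frequency grid does not resolve both bands")
    return float(coh.coherence[in_theta].mean() / coh.coherence[out_theta].mean())


def band_power(spec: SpectralEstimate, band: tuple[float, float]) -> float:
    """Mean power (dB) over [band[0], band[1]]."""
    lo, hi = band
    m = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not m.any() or lo < spec.freqs[0] or hi > spec.freqs[-1]:
        raise ValueError(f"band {band} outside frequency grid")
    return float(spec.power_db[m].mean())


def theta_summary(spec_x: SpectralEstimate, spec_y: SpectralEstimate,
                  coh: CoherenceEstimate,
                  config: AnalysisConfig | None = None,
                  labels: tuple[str, str] = ("x", "y")) -> ThetaSummary:
    cfg = config or AnalysisConfig()
    band = cfg.theta_band
    m = (coh.freqs >= band[0]) & (coh.freqs <= band[1])
    return ThetaSummary(
        {labels[0]: band_power(spec_x, band), labels[1]: band_power(spec_y, band)},
        float(coh.coherence[m].mean()), theta_ratio(coh, cfg))
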