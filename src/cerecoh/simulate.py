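"""Synthetic recordings with the statistical structure the analysis assumes.

Every generator is a pure function of its parameters and seed: identical
inputs give bit-identical output.  Ground truth (coupling direction and
delay, true locomotion bouts, programmed response category, cluster labels)
is always returned alongside the data so downstream stages can be verified
without circularity.

The LFP model is a noise-driven AR(2) resonance in the theta band (5–10 Hz)
on top of a 1/f background — not a pure sinusoid — so that coherence stays
below 1 and jackknife error bars are exercised.  Directed coupling feeds the
*theta-oscillator component* of the source channel, delayed, into the target:
this reproduces the band-selective coherence seen between deep-cerebellar and
prefrontal field potentials; coupling the full broadband signal would instead
produce frequency-flat coherence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import ContinuousSignal, EpochSet, SpeedTrace, SpikeTrain, StimProtocol

__all__ = [
    "CoupledLFPParams", "UnitProfileParams", "SpeedBoutParams",
    "gen_coupled_lfp", "gen_speed_trace", "gen_stim_protocol",
    "gen_unit_spikes", "gen_slow_wave_spikes", "gen_evoked_lfp",
    "gen_cluster_features", "gen_mean_waveform", "theta_oscillator",
    "one_over_f_noise", "evoked_template",
]


# ------------------------------------------------------------------ params

@dataclass
class CoupledLFPParams:
    """Two theta-coupled LFP channels.

    ``coupling_gain`` scales the delayed source oscillator added to the
    target; the default places theta coherence in a detectable mid-range
    (~0.4–0.7) — the underlying physiological coupling strength is unknown
    and this value is an arbitrary, documented choice.  ``coupling_delay``
    defaults to 13 ms, matching the conduction latency scale of the
    cerebello-prefrontal pathway.
    """

    duration: float = 60.0
    fs: float = 2000.0
    theta_freq: float = 7.0            # Hz, within 5-10
    coupling_gain: float = 0.8
    coupling_delay: float = 0.013      # s
    direction: str = "x_to_y"          # {x_to_y, y_to_x, none}
    noise_1f_exponent: float = 1.0
    snr: float = 1.0                   # oscillator RMS / background RMS
    amplitude_uv: float = 50.0
    resonance_bw: float = 2.0          # Hz, -3 dB width of the AR(2) peak
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.direction not in ("x_to_y", "y_to_x", "none"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.coupling_gain > 0 and self.direction != "none" \
                and self.coupling_delay < 1.0 / self.fs:
            raise ValueError("coupling_delay shorter than one sample")


@dataclass
class UnitProfileParams:
    """Programmed peri-stimulus response of one unit.

    ``modulation_depth`` is a fraction of baseline: a decrease of depth 0.7
    drops the rate to 30% of baseline during the train, matching the scale
    of suppression observed in prelimbic cells.  The biphasic profile is
    suppression during the 1-s train followed by a rebound excitation bump
    centred ``rebound_lag`` after train onset; rebound excitations in the
    recorded populations are large (several-fold the baseline rate), so the
    rebound peak has its own gain, ``rebound_gain`` × baseline above
    baseline, independent of the suppression depth.
    """

    category: str = "none"             # {increase, decrease, biphasic, none}
    baseline_rate: float = 5.0         # Hz
    modulation_depth: float = 0.7
    onset_lag: float = 0.0             # s after train onset
    rebound_lag: float = 2.0           # s after train onset (biphasic peak)
    rebound_width: float = 0.25        # s (SD of the rebound bump)
    rebound_gain: float = 2.0          # peak rebound excess, x baseline
    seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in ("increase", "decrease", "biphasic", "none"):
            raise ValueError(f"unknown category {self.category!r}")
        if not self.baseline_rate > 0:
            raise ValueError("baseline_rate must be positive")
        if not 0 <= self.modulation_depth <= 10:
            raise ValueError("modulation_depth out of range [0, 10]")


@dataclass
class SpeedBoutParams:
    """Alternating rest/locomotion bouts of video-tracked speed."""

    duration: float = 300.0
    fs_video: float = 25.0
    bout_rate: float = 3.0             # locomotion bouts per minute
    mean_bout_length: float = 8.0      # s
    rest_speed: float = 1.0            # tracker units
    run_speed: float = 8.0
    rest_jitter: float = 0.4
    run_jitter: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.run_speed > self.rest_speed >= 0:
            raise ValueError("need run_speed > rest_speed >= 0")


# ------------------------------------------------------------- LFP pieces

def theta_oscillator(n: int, fs: float, freq: float, bw: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise-driven AR(2) resonance at ``freq`` Hz."""
    rho = 1.0 - np.pi * bw / fs
    a = [1.0, -2.0 * rho * np.cos(2 * np.pi * freq / fs), rho ** 2]
    x = sps.lfilter([1.0], a, rng.standard_normal(n + int(5 * fs)))
    x = x[int(5 * fs):]                       # drop filter transient
    return x / x.std()


def one_over_f_noise(n: int, fs: float, exponent: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f**exponent (flat < 1 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.maximum(f, 1.0) ** (-exponent / 2.0)
    shape[0] = 0.0                            # remove DC
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def gen_coupled_lfp(params: CoupledLFPParams) -> tuple[ContinuousSignal,
                                                       ContinuousSignal, dict]:
    """Two LFP channels with optional unidirectional delayed theta coupling.

    Returns ``(x, y, truth)`` where truth records direction, delay and gain.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fs))
    osc_x = theta_oscillator(n, params.fs, params.theta_freq, params.resonance_bw, rng)
    osc_y = theta_oscillator(n, params.fs, params.theta_freq, params.resonance_bw, rng)
    bg_x = one_over_f_noise(n, params.fs, params.noise_1f_exponent, rng)
    bg_y = one_over_f_noise(n, params.fs, params.noise_1f_exponent, rng)
    x = params.snr * osc_x + bg_x
    y = params.snr * osc_y + bg_y
    d = int(round(params.coupling_delay * params.fs))
    if params.coupling_gain > 0 and params.direction != "none":
        src = osc_x if params.direction == "x_to_y" else osc_y
        add = np.zeros(n)
        add[d:] = params.coupling_gain * params.snr * src[:-d]
        if params.direction == "x_to_y":
            y = y + add
        else:
            x = x + add
    scale = params.amplitude_uv
    truth = {"direction": params.direction, "delay_s": params.coupling_delay,
             "delay_samples": d, "gain": params.coupling_gain}
    return (ContinuousSignal(scale * x, fs=params.fs, label="x"),
            ContinuousSignal(scale * y, fs=params.fs, label="y"), truth)


# ------------------------------------------------------------------ speed

def gen_speed_trace(params: SpeedBoutParams) -> tuple[SpeedTrace, EpochSet]:
    """Rest/locomotion speed trace plus the true locomotion EpochSet."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fs_video))
    t = np.arange(n) / params.fs_video
    speed = np.maximum(0.0, params.rest_speed
                       + params.rest_jitter * rng.standard_normal(n))
    bouts = []
    if params.bout_rate > 0:
        mean_rest = max(60.0 / params.bout_rate - params.mean_bout_length, 1.0)
        tcur = rng.exponential(mean_rest)
        while tcur < params.duration:
            blen = rng.gamma(4.0, params.mean_bout_length / 4.0)
            b0, b1 = tcur, min(tcur + blen, params.duration)
            if b1 - b0 > 2.0 / params.fs_video:
                bouts.append((b0, b1))
                m = (t >= b0) & (t < b1)
                speed[m] = np.maximum(
                    0.0, params.run_speed + params.run_jitter
                    * rng.standard_normal(int(m.sum())))
            tcur = b1 + rng.exponential(mean_rest)
    truth = EpochSet(np.array(bouts).reshape(-1, 2), "locomotion")
    return SpeedTrace(t, speed, params.fs_video), truth


# --------------------------------------------------------------- protocol

def gen_stim_protocol(pattern: str, n_events: int, intensity: float = 100.0,
                      t_first: float = 5.0) -> StimProtocol:
    """Stimulation timing for the two protocols used throughout.

    ``triplet``: bursts of 3 pulses 3 ms apart, one burst every 2 s (field
    potential protocol).  ``train``: 100 pulses at 100 Hz (1 s trains), one
    train every 5 s (single-unit protocol).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if pattern == "triplet":
        ppe, ipi, period = 3, 0.003, 2.0
    elif pattern == "train":
        ppe, ipi, period = 100, 0.01, 5.0
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    onsets = t_first + period * np.arange(n_events)
    pulses = (onsets[:, None] + ipi * np.arange(ppe)[None, :]).ravel()
    return StimProtocol(pulses, onsets, intensity, pattern, ppe, ipi)


# ------------------------------------------------------------ spike trains

def _thinned_poisson(rate_fn, bound: float, span: tuple[float, float],
                     rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson spikes by thinning against a bounded rate."""
    t0, t1 = span
    n_cand = rng.poisson(bound * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n_cand))
    lam = np.clip(rate_fn(cand), 0.0, None)
    keep = rng.uniform(0.0, bound, cand.size) < lam
    times = cand[keep]
    return np.unique(times)


def gen_unit_spikes(profile: UnitProfileParams, protocol: StimProtocol) -> SpikeTrain:
    """Spike train with a programmed stimulus-locked response profile.

    Rate function: baseline between events.  ``decrease``/``increase``
    multiply the rate by ``1 ∓/± depth`` for 1 s from ``onset_lag`` after
    each train onset; ``biphasic`` suppresses during the train and adds a
    Gaussian rebound bump centred at ``rebound_lag``; ``none`` is unchanged.
    """
    onsets = protocol.train_onsets
    span = (float(onsets[0] - 3.0), float(protocol.pulse_times[-1] + 6.0))
    lam0, depth = profile.baseline_rate, profile.modulation_depth
    cat = profile.category

    def rate_fn(t: np.ndarray) -> np.ndarray:
        lam = np.full(t.shape, lam0)
        idx = np.searchsorted(onsets, t, side="right") - 1
        valid = idx >= 0
        dt = np.where(valid, t - onsets[np.clip(idx, 0, None)], np.inf)
        if cat == "decrease":
            m = (dt >= profile.onset_lag) & (dt < profile.onset_lag + 1.0)
            lam[m] = lam0 * (1.0 - min(depth, 1.0))
        elif cat == "increase":
            m = (dt >= profile.onset_lag) & (dt < profile.onset_lag + 1.0)
            lam[m] = lam0 * (1.0 + depth)
        elif cat == "biphasic":
            m = (dt >= 0.0) & (dt < 1.0)
            lam[m] = lam0 * (1.0 - min(depth, 1.0))
            gain = profile.rebound_gain if depth > 0 else 0.0
            w = (dt >= 1.0) & (dt < 4.5)
            lam[w] = lam0 * (1.0 + gain * np.exp(
                -0.5 * ((dt[w] - profile.rebound_lag) / profile.rebound_width) ** 2))
        return lam

    bound = lam0 * (1.0 + max(depth, 0.0) + profile.rebound_gain) + 1e-12
    rng = np.random.default_rng(profile.seed)
    times = _thinned_poisson(rate_fn, bound, span, rng)
    return SpikeTrain(f"sim_{cat}", times, span)


def gen_slow_wave_spikes(n_units: int, modulation_freq: float = 1.0,
                         depth: float = 0.8, duration: float = 200.0,
                         seed: int = 0, base_rate: float = 5.0,
                         phase_drift: float = 0.8,
                         suppress_epochs: EpochSet | None = None) -> list[SpikeTrain]:
    """Units sharing a common ~1 Hz sinusoidal rate modulation.

    Emulates slow-wave co-modulation under urethane anesthesia.  The shared
    oscillation carries Brownian phase drift (``phase_drift`` rad/√s), so it
    is *not* locked to any stimulation schedule — as in the real state —
    and the shuffle predictor cannot absorb it, while local periodicity at
    ±1/modulation_freq survives.  Within ``suppress_epochs`` the common
    modulation is removed (rate at baseline), emulating stimulation-induced
    disruption of the slow oscillation.
    """
    if not 0 <= depth <= 1:
        raise ValueError("depth must lie in [0, 1]")
    span = (0.0, float(duration))
    omega = 2 * np.pi * modulation_freq
    dt = 0.01
    rng_phase = np.random.default_rng((seed, "phase".encode().hex()))
    grid = np.arange(0.0, duration + dt, dt)
    drift = np.cumsum(phase_drift * np.sqrt(dt)
                      * rng_phase.standard_normal(grid.size))

    def rate_fn(t: np.ndarray) -> np.ndarray:
        phi = omega * t + np.interp(t, grid, drift)
        lam = base_rate * (1.0 + depth * np.sin(phi))
        if suppress_epochs is not None and len(suppress_epochs):
            off = np.zeros(t.shape, bool)
            for a, b in suppress_epochs:
                off |= (t >= a) & (t < b)
            lam[off] = base_rate
        return lam

    trains = []
    for i in range(n_units):
        rng = np.random.default_rng((seed, i))
        times = _thinned_poisson(rate_fn, base_rate * (1 + depth) + 1e-12,
                                 span, rng)
        trains.append(SpikeTrain(f"sw{i:02d}", times, span))
    return trains


# ------------------------------------------------------------ evoked LFP

def evoked_template(fs: float, onset_s: float = 0.013, peak_uv: float = 150.0,
                    trough_uv: float = -80.0, rise_s: float = 0.007,
                    fall_s: float = 0.013, recover_s: float = 0.040) -> np.ndarray:
    """Deterministic biphasic evoked-field template, time-locked to t=0.

    Zero until ``onset_s``, cosine rise to ``peak_uv``, cosine fall to
    ``trough_uv``, cosine recovery to zero.  Default peak-to-trough is
    230 µV (0.23 mV), the amplitude scale of the prelimbic evoked field.
    """
    n = int(round((onset_s + rise_s + fall_s + recover_s) * fs)) + 1
    t = np.arange(n) / fs
    w = np.zeros(n)
    u = (t - onset_s) / rise_s
    m = (u >= 0) & (u < 1)
    w[m] = peak_uv * (1 - np.cos(np.pi * u[m])) / 2
    v = (t - onset_s - rise_s) / fall_s
    m = (v >= 0) & (v < 1)
    w[m] = trough_uv + (peak_uv - trough_uv) * (1 + np.cos(np.pi * v[m])) / 2
    r = (t - onset_s - rise_s - fall_s) / recover_s
    m = (r >= 0) & (r <= 1)
    w[m] = trough_uv * (1 + np.cos(np.pi * r[m])) / 2
    return w


def gen_evoked_lfp(n_trials: int = 72, onset_ms: float = 13.0,
                   amp_uv: float = 230.0, noise_sd: float = 40.0,
                   protocol: StimProtocol | None = None, fs: float = 2000.0,
                   artifact_uv: float = 2000.0, seed: int = 0,
                   ) -> tuple[ContinuousSignal, StimProtocol, dict]:
    """Continuous LFP with a stereotyped evoked field after each burst.

    The template is inserted ``onset_ms`` after each event's *final* pulse;
    one-sample stimulus artifacts of ±``artifact_uv`` are placed at every
    pulse time so artifact blanking can be exercised.  Returns the signal,
    the protocol used, and a truth record (onset, amplitude, template).
    """
    if protocol is None:
        protocol = gen_stim_protocol("triplet", n_trials)
    rng = np.random.default_rng(seed)
    t_end = protocol.pulse_times[-1] + 1.0
    n = int(round(t_end * fs))
    base = evoked_template(fs, onset_s=onset_ms / 1000.0)
    tpl = base * (amp_uv / (base.max() - base.min()))
    if tpl.size / fs >= np.min(np.diff(protocol.train_onsets, prepend=-np.inf)[1:],
                               initial=np.inf):
        raise ValueError("evoked template longer than inter-event interval")
    x = noise_sd * rng.standard_normal(n) if noise_sd > 0 else np.zeros(n)
    for tref in protocol.event_final_pulses():
        i0 = int(round(tref * fs))
        x[i0:i0 + tpl.size] += tpl[: max(0, min(tpl.size, n - i0))]
    for tp in protocol.pulse_times:
        i = int(round(tp * fs))
        if 0 <= i < n - 1:
            x[i] += artifact_uv
            x[i + 1] -= artifact_uv
    truth = {"onset_ms": onset_ms, "peak_to_trough_uv": amp_uv, "template": tpl}
    return ContinuousSignal(x, fs=fs, label="evoked"), protocol, truth


# ------------------------------------------------------- cluster features

def gen_cluster_features(n_units: int = 3, n_noise: int = 2000, dim: int = 8,
                         separation: float = 8.0, n_per_cluster: int = 300,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian tetrode-feature clusters plus a background noise cloud.

    Cluster means sit ``separation`` Mahalanobis units (unit covariance)
    from the noise-cloud centre along random directions.  Returns
    ``(features, labels)``; label -1 marks noise, 0..n_units-1 the clusters.
    Every row belongs to exactly one label.
    """
    if n_noise <= n_per_cluster:
        raise ValueError("need n_noise > cluster size")
    rng = np.random.default_rng(seed)
    rows = [rng.standard_normal((n_noise, dim))]
    labels = [np.full(n_noise, -1)]
    for k in range(n_units):
        u = rng.standard_normal(dim)
        u /= np.linalg.norm(u)
        rows.append(separation * u + rng.standard_normal((n_per_cluster, dim)))
        labels.append(np.full(n_per_cluster, k))
    return np.vstack(rows), np.concatenate(labels)


def gen_mean_waveform(trough_to_peak_ms: float = 0.5, fs: float = 32000.0,
                      amp_uv: float = 100.0, duration_ms: float = 2.0) -> np.ndarray:
    """Stylized mean extracellular spike waveform (negative trough first)."""
    n = int(round(duration_ms * 1e-3 * fs))
    t = np.arange(n) / fs * 1e3            # ms
    t0 = 0.4
    w = -amp_uv * np.exp(-0.5 * ((t - t0) / 0.08) ** 2)
    w += 0.35 * amp_uv * np.exp(-0.5 * ((t - t0 - trough_to_peak_ms)
                                        / (0.25 * max(trough_to_peak_ms, 0.1))) ** 2)
    return w
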