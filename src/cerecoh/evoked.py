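"""Stimulus-triggered field-potential averaging and response metrics.

Trials are aligned to each event's *final* pulse, so onset latencies are
measured clear of the stimulus burst.  Samples within ±1 ms of any pulse
are blanked (excluded from the average and linearly interpolated for
display), removing stimulus artifacts without touching the inter-pulse
signal of 3-ms-spaced bursts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .core import ContinuousSignal, StimProtocol

__all__ = ["EvokedAverage", "EvokedMetrics", "average_evoked", "onset_latency",
           "peak_to_trough", "normalize_by_depth", "evoked_metrics"]


@dataclass
class EvokedAverage:
    time: np.ndarray            # s relative to the reference (final) pulse
    mean: np.ndarray            # µV, blanked samples interpolated
    sem: np.ndarray             # µV
    n_trials: int
    blanked: np.ndarray         # bool mask of blanked time points
    fs: float


@dataclass
class EvokedMetrics:
    onset_latency_ms: float | None
    peak_to_trough_mv: float
    depth_label: str = ""
    normalized_amplitude: float | None = None   # % of maximum across depths


def average_evoked(signal: ContinuousSignal, protocol: StimProtocol,
                   window: tuple[float, float] = (-0.06, 0.15),
                   config: AnalysisConfig | None = None) -> EvokedAverage:
    """Trial average aligned to each event's final pulse.

    Events whose window is clipped by the recording edge are dropped with a
    warning; blanked samples around pulses are excluded from mean and SEM
    and linearly interpolated in the returned trace.
    """
    import warnings
    cfg = config or AnalysisConfig()
    if protocol.n_events == 0:
        raise ValueError("protocol has no events")
    fs = signal.fs
    i_lo = int(round(window[0] * fs))
    i_hi = int(round(window[1] * fs))
    n_t = i_hi - i_lo
    rel_t = (np.arange(i_lo, i_hi)) / fs
    trials = []
    blank = np.zeros(n_t, bool)
    refs = protocol.event_final_pulses()
    burst = protocol.event_duration()
    for tref in refs:
        c = int(round((tref - signal.t_start) * fs))
        if c + i_lo < 0 or c + i_hi > signal.n_samples:
            warnings.warn(f"event at {tref:.3f}s clipped by recording edge; dropped")
            continue
        trials.append(signal.samples[c + i_lo:c + i_hi])
        for dp in np.arange(-burst, 1e-12, protocol.intra_event_interval) \
                if protocol.pulses_per_event > 1 else [0.0]:
            blank |= np.abs(rel_t - dp) <= cfg.blank_half_width + 0.5 / fs
    if not trials:
        raise ValueError("no usable trials (all windows clipped)")
    arr = np.asarray(trials)
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 \
        else np.zeros(n_t)
    # interpolate across blanked stretches for display/metrics
    if blank.any() and not blank.all():
        good = ~blank
        mean = mean.copy()
        mean[blank] = np.interp(rel_t[blank], rel_t[good], mean[good])
        sem = sem.copy()
        sem[blank] = np.interp(rel_t[blank], rel_t[good], sem[good])
    return EvokedAverage(rel_t, mean, sem, arr.shape[0], blank, fs)


def onset_latency(evoked: EvokedAverage,
                  baseline_window: tuple[float, float] | None = None,
                  k_sd: float | None = None,
                  n_consecutive: int | None = None,
                  config: AnalysisConfig | None = None) -> float | None:
    """First post-reference time (ms) where the average deviates from
    baseline by more than k_sd baseline SDs for >= n_consecutive samples.

    Returns None when the criterion is never met.  Blanked samples around
    the reference pulse are skipped.  A noise-free baseline (SD = 0) uses a
    zero threshold with strict inequality, so any true deflection is
    detected at its first nonzero sample.

    The threshold crossing *detects* the response; the reported onset is
    localized by walking back from the crossing until the trace re-enters
    the baseline noise band (within half a baseline SD of the baseline
    mean).  This removes the crossing-delay bias of a pure threshold rule
    without letting chance runs of like-signed baseline noise drag the
    onset earlier.
    """
    cfg = config or AnalysisConfig()
    bw = baseline_window or cfg.evoked_baseline
    k = k_sd if k_sd is not None else cfg.onset_k_sd
    nc = n_consecutive if n_consecutive is not None else cfg.onset_n_consecutive
    if bw[1] > 0:
        raise ValueError("baseline window must precede the reference pulse")
    bmask = (evoked.time >= bw[0]) & (evoked.time < bw[1]) & ~evoked.blanked
    if bmask.sum() < 2:
        raise ValueError("baseline window contains fewer than 2 usable samples")
    b_mean = evoked.mean[bmask].mean()
    b_sd = evoked.mean[bmask].std(ddof=1)
    post = (evoked.time > 0) & ~evoked.blanked
    idx = np.flatnonzero(post)
    delta = evoked.mean[idx] - b_mean
    dev = np.abs(delta) > k * b_sd
    run = 0
    for j, d in enumerate(dev):
        run = run + 1 if d else 0
        if run >= nc:
            j0 = j - nc + 1
            sign = np.sign(delta[j0])
            floor = 0.5 * b_sd
            while j0 > 0 and sign * delta[j0 - 1] > floor:
                j0 -= 1
            return float(evoked.time[idx[j0]] * 1000.0)
    return None


def peak_to_trough(evoked: EvokedAverage,
                   search_window: tuple[float, float] | None = None,
                   config: AnalysisConfig | None = None) -> float:
    """max − min of the average within the post-reference window, in mV."""
    cfg = config or AnalysisConfig()
    lo, hi = search_window or cfg.p2t_window
    if lo < evoked.time[0] or hi > evoked.time[-1] + 1e-12:
        raise ValueError("search window outside evoked span")
    m = (evoked.time >= lo) & (evoked.time <= hi)
    if not m.any():
        raise ValueError("empty search window")
    seg = evoked.mean[m]
    return float((seg.max() - seg.min()) / 1000.0)


def normalize_by_depth(metrics: list[EvokedMetrics]) -> list[EvokedMetrics]:
    """Express each amplitude as % of the maximum across depths (ties share
    100)."""
    if not metrics:
        raise ValueError("need at least one metric")
    amps = np.array([m.peak_to_trough_mv for m in metrics])
    mx = amps.max()
    if mx <= 0:
        raise ValueError("all amplitudes are zero; normalization undefined")
    for m in metrics:
        m.normalized_amplitude = float(100.0 * m.peak_to_trough_mv / mx)
    return metrics


def evoked_metrics(signal: ContinuousSignal, protocol: StimProtocol,
                   depth_label: str = "",
                   config: AnalysisConfig | None = None) -> EvokedMetrics:
    """Average, then measure onset latency and peak-to-trough amplitude."""
    ev = average_evoked(signal, protocol, config=config)
    return EvokedMetrics(onset_latency(ev, config=config),
                         peak_to_trough(ev, config=config), depth_label)
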