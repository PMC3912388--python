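"""Behavioral-state segmentation from running speed and cortical LFP.

Locomotion is defined as z-score-normalized running speed greater than the
threshold (default 0); quiet rest additionally requires the absence of
frontal sleep-spindle activity (10–15 Hz envelope bursts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig
from .core import ContinuousSignal, EpochSet, SpeedTrace

__all__ = ["StateSegmentation", "zscore_speed", "extract_locomotion_epochs",
           "detect_spindles", "detect_rest_epochs", "segment_states"]


@dataclass
class StateSegmentation:
    locomotion: EpochSet
    rest: EpochSet
    speed_z: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.locomotion.overlap(self.rest) > 1e-9:
            raise ValueError("locomotion and rest epochs overlap")

    @property
    def coverage(self) -> float:
        span = self.times[-1] - self.times[0] if self.times.size > 1 else 0.0
        if span <= 0:
            return 0.0
        return min(1.0, (self.locomotion.total_duration
                         + self.rest.total_duration) / span)


def zscore_speed(speed: SpeedTrace) -> np.ndarray:
    """Z-score the speed trace using the whole-session population SD."""
    if speed.speed.size < 2:
        raise ValueError("need at least 2 speed samples")
    sd = speed.speed.std()          # population (ddof=0) convention
    if sd == 0:
        raise ValueError("zero-variance speed trace: z-score undefined")
    return (speed.speed - speed.speed.mean()) / sd


def _merge_and_prune(epochs: EpochSet, gap_merge: float, min_duration: float,
                     label: str) -> EpochSet:
    iv = epochs.intervals
    merged: list[list[float]] = []
    for t0, t1 in iv:
        if merged and t0 - merged[-1][1] <= gap_merge:
            merged[-1][1] = t1
        else:
            merged.append([t0, t1])
    keep = [(a, b) for a, b in merged if b - a >= min_duration]
    return EpochSet(np.array(keep).reshape(-1, 2), label)


def extract_locomotion_epochs(z_speed: np.ndarray, times: np.ndarray,
                              min_duration: float = 1.0, gap_merge: float = 0.5,
                              threshold: float = 0.0) -> EpochSet:
    """Maximal runs with z > threshold; short gaps merged, short runs dropped."""
    runs = EpochSet.from_mask(np.asarray(z_speed) > threshold, times, "locomotion")
    return _merge_and_prune(runs, gap_merge, min_duration, "locomotion")


def detect_spindles(frontal_lfp: ContinuousSignal,
                    config: AnalysisConfig | None = None) -> EpochSet:
    """Sleep-spindle intervals: 10–15 Hz Hilbert envelope > mean + z·SD
    sustained for the minimum duration, padded on both sides."""
    cfg = config or AnalysisConfig()
    lo, hi = cfg.spindle_band
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=frontal_lfp.fs, output="sos")
    filt = sps.sosfiltfilt(sos, frontal_lfp.samples)
    env = np.abs(sps.hilbert(filt))
    thr = env.mean() + cfg.spindle_z * env.std()
    t = frontal_lfp.times()
    runs = EpochSet.from_mask(env > thr, t, "spindle")
    keep = [(max(t[0], a - cfg.spindle_pad), b + cfg.spindle_pad)
            for a, b in runs if b - a >= cfg.spindle_min_duration]
    # pad may make neighbours overlap; merge
    out: list[list[float]] = []
    for a, b in keep:
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return EpochSet(np.array(out).reshape(-1, 2), "spindle")


def _subtract(base: EpochSet, remove: EpochSet, label: str) -> EpochSet:
    out = []
    for a, b in base:
        segs = [(a, b)]
        for r0, r1 in remove:
            new = []
            for s0, s1 in segs:
                if r1 <= s0 or r0 >= s1:
                    new.append((s0, s1))
                else:
                    if r0 > s0:
                        new.append((s0, r0))
                    if r1 < s1:
                        new.append((r1, s1))
            segs = new
        out.extend(segs)
    return EpochSet(np.array(out).reshape(-1, 2), label)


def detect_rest_epochs(z_speed: np.ndarray, times: np.ndarray,
                       frontal_lfp: ContinuousSignal | None = None,
                       config: AnalysisConfig | None = None) -> EpochSet:
    """Quiet-rest epochs: z ≤ threshold and no frontal spindle activity."""
    cfg = config or AnalysisConfig()
    rest = EpochSet.from_mask(np.asarray(z_speed) <= cfg.speed_z_threshold,
                              times, "rest")
    rest = _merge_and_prune(rest, cfg.gap_merge, cfg.min_bout_duration, "rest")
    if frontal_lfp is not None:
        spindles = detect_spindles(frontal_lfp, cfg)
        if len(spindles):
            rest = _subtract(rest, spindles, "rest")
            rest = _merge_and_prune(rest, 0.0, cfg.min_bout_duration, "rest")
    return rest


def segment_states(speed: SpeedTrace, frontal_lfp: ContinuousSignal | None = None,
                   config: AnalysisConfig | None = None) -> StateSegmentation:
    """Full segmentation into locomotion and quiet-rest epochs."""
    cfg = config or AnalysisConfig()
    z = zscore_speed(speed)
    loco = extract_locomotion_epochs(z, speed.times, cfg.min_bout_duration,
                                     cfg.gap_merge, cfg.speed_z_threshold)
    rest = detect_rest_epochs(z, speed.times, frontal_lfp, cfg)
    if len(loco):
        rest = _subtract(rest, loco, "rest")
        rest = _merge_and_prune(rest, 0.0, cfg.min_bout_duration, "rest")
    return StateSegmentation(loco, rest, z, speed.times)
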