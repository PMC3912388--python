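"""Core domain types shared by every analysis stage.

All times are in seconds, referenced to recording start (t = 0).  Intervals
are half-open ``[t0, t1)`` so that epochs concatenate without overlap.
Voltages are treated as microvolts by convention; no absolute calibration is
asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContinuousSignal",
    "SpikeTrain",
    "StimProtocol",
    "SpeedTrace",
    "EpochSet",
    "ValidationError",
]


class ValidationError(ValueError):
    """A domain-type invariant was violated."""


@dataclass
class ContinuousSignal:
    """Uniformly sampled voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in microvolts.
    fs : float
        Sampling rate in Hz.
    t_start : float
        Time of the first sample, seconds.
    label : str
        Channel name (e.g. ``"FN"`` or ``"PrL"``).
    band : tuple of float
        (low, high) acquisition filter band in Hz; metadata only.
    """

    samples: np.ndarray
    fs: float
    t_start: float = 0.0
    label: str = ""
    band: tuple[float, float] = (0.1, 475.0)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("signal must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        bad = np.flatnonzero(~np.isfinite(self.samples))
        if bad.size:
            raise ValidationError(
                f"non-finite sample at index {bad[0]} (of {bad.size} total)"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t_start + np.arange(self.n_samples) / self.fs

    def slice(self, t0: float, t1: float) -> np.ndarray:
        """Samples within [t0, t1)."""
        i0 = max(0, int(np.ceil((t0 - self.t_start) * self.fs - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil((t1 - self.t_start) * self.fs - 1e-9)))
        return self.samples[i0:i1]


@dataclass
class SpikeTrain:
    """Ascending spike timestamps for one isolated unit."""

    unit_id: str
    times: np.ndarray
    span: tuple[float, float]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValidationError("spike times must be 1-D")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"unit {self.unit_id}: times not strictly ascending")
        t0, t1 = self.span
        if not t1 > t0:
            raise ValidationError(f"unit {self.unit_id}: empty span {self.span}")
        if self.times.size and (self.times[0] < t0 or self.times[-1] > t1):
            raise ValidationError(f"unit {self.unit_id}: spikes outside span")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    @property
    def mean_rate(self) -> float:
        t0, t1 = self.span
        return self.n_spikes / (t1 - t0)

    def in_window(self, t0: float, t1: float) -> np.ndarray:
        """Spike times within [t0, t1)."""
        i0, i1 = np.searchsorted(self.times, [t0, t1])
        return self.times[i0:i1]


@dataclass
class StimProtocol:
    """Stimulation pulse/event timing.

    ``pattern`` is ``"triplet"`` (3 pulses, 3 ms apart, one burst per event)
    or ``"train"`` (100 pulses at 100 Hz, one train per event).  Every pulse
    belongs to exactly one event.
    """

    pulse_times: np.ndarray
    train_onsets: np.ndarray
    intensity: float
    pattern: str
    pulses_per_event: int
    intra_event_interval: float

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        self.train_onsets = np.asarray(self.train_onsets, dtype=float)
        if self.pulse_times.size and np.any(np.diff(self.pulse_times) <= 0):
            raise ValidationError("pulse times not strictly ascending")
        if self.intensity < 0:
            raise ValidationError("intensity must be nonnegative")
        if self.pattern not in ("triplet", "train"):
            raise ValidationError(f"unknown pattern {self.pattern!r}")
        if self.pulse_times.size != self.train_onsets.size * self.pulses_per_event:
            raise ValidationError("pulse count does not match events × pulses/event")

    @property
    def n_events(self) -> int:
        return self.train_onsets.size

    def event_final_pulses(self) -> np.ndarray:
        """Time of the last pulse of each event (the evoked reference pulse)."""
        return self.pulse_times.reshape(self.n_events, self.pulses_per_event)[:, -1]

    def event_duration(self) -> float:
        """Span from first to last pulse within one event."""
        return (self.pulses_per_event - 1) * self.intra_event_interval


@dataclass
class SpeedTrace:
    """Video-tracked running speed (tracker units, nonnegative)."""

    times: np.ndarray
    speed: np.ndarray
    fs_video: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.times.shape != self.speed.shape:
            raise ValidationError("times and speed must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("speed times not strictly ascending")
        if np.any(self.speed < 0):
            raise ValidationError("speed must be nonnegative")
        if not self.fs_video > 0:
            raise ValidationError("fs_video must be positive")


@dataclass
class EpochSet:
    """Sorted, non-overlapping half-open intervals labelled with a state."""

    intervals: np.ndarray
    state_label: str = ""

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if iv.size and np.any(iv[:, 1] <= iv[:, 0]):
            raise ValidationError("epoch with t1 <= t0")
        if iv.shape[0] > 1:
            order = np.argsort(iv[:, 0])
            iv = iv[order]
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValidationError("overlapping epochs")
        self.intervals = iv

    def __len__(self) -> int:
        return self.intervals.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.intervals))

    @property
    def total_duration(self) -> float:
        if not len(self):
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def overlap(self, other: "EpochSet") -> float:
        """Total length of the intersection with ``other`` (seconds)."""
        tot = 0.0
        for a0, a1 in self:
            for b0, b1 in other:
                tot += max(0.0, min(a1, b1) - max(a0, b0))
        return tot

    @staticmethod
    def from_mask(mask: np.ndarray, times: np.ndarray, state_label: str = "") -> "EpochSet":
        """Build epochs from a boolean mask over sample times.

        Each maximal run of True becomes one interval; the interval closes at
        the time following the last True sample (half-open convention).
        """
        mask = np.asarray(mask, dtype=bool)
        if mask.size == 0 or not mask.any():
            return EpochSet(np.empty((0, 2)), state_label)
        d = np.diff(mask.astype(int))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if mask[0]:
            starts = np.r_[0, starts]
        if mask[-1]:
            ends = np.r_[ends, mask.size]
        dt = times[1] - times[0] if times.size > 1 else 0.0
        t_end = np.where(ends < times.size, times[np.minimum(ends, times.size - 1)],
                         times[-1] + dt)
        return EpochSet(np.column_stack([times[starts], t_end]), state_label)
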