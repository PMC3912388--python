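"""File readers/writers for the package's record types.

Two on-disk representations are supported:

* plain CSV (header row, UTF-8) for every tabular record, and
* a hierarchical HDF5 container for continuous signals (one group per
  channel with ``fs`` / ``t_start`` / ``band`` attributes).

Vendor acquisition formats are deliberately unsupported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (ContinuousSignal, EpochSet, SpeedTrace, SpikeTrain,
                   StimProtocol, ValidationError)

__all__ = [
    "read_signal", "write_signal", "read_spikes", "write_spikes",
    "read_protocol", "write_protocol", "read_speed", "write_speed",
    "read_epochs", "write_epochs", "validate_alignment", "AlignmentReport",
]

log = logging.getLogger("cerecoh.io")


# ---------------------------------------------------------------- signals

def write_signal(signal: ContinuousSignal, path: str | Path,
                 format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "container")
    if fmt == "csv":
        df = pd.DataFrame({"sample_uv": signal.samples})
        with open(path, "w") as fh:
            fh.write(f"# fs={signal.fs!r} t_start={signal.t_start!r} "
                     f"label={signal.label} band={signal.band[0]!r},{signal.band[1]!r}\n")
            df.to_csv(fh, index=False)
    elif fmt == "container":
        with h5py.File(path, "a") as h5:
            name = signal.label or "signal"
            if name in h5:
                del h5[name]
            g = h5.create_group(name)
            g.create_dataset("samples", data=signal.samples)
            g.attrs["fs"] = signal.fs
            g.attrs["t_start"] = signal.t_start
            g.attrs["band"] = list(signal.band)
    else:
        raise ValueError(f"unknown signal format {fmt!r}")


def read_signal(path: str | Path, format: str | None = None,
                channel: str | None = None, fs: float | None = None) -> ContinuousSignal:
    """Read a continuous signal from CSV or the HDF5 container.

    CSV files carry rate metadata in a leading ``#`` comment line; if absent,
    ``fs`` must be given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "container")
    if fmt == "csv":
        meta: dict[str, str] = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                body = fh.read()
            else:
                body = first + fh.read()
        if not body.strip():
            raise ValidationError(f"{path}: empty file")
        from io import StringIO
        df = pd.read_csv(StringIO(body))
        rate = fs if fs is not None else (float(meta["fs"]) if "fs" in meta else None)
        if rate is None:
            raise ValidationError(f"{path}: missing sampling-rate metadata")
        band = tuple(float(x) for x in meta.get("band", "0.1,475").split(","))
        return ContinuousSignal(df.iloc[:, 0].to_numpy(float), fs=rate,
                                t_start=float(meta.get("t_start", 0.0)),
                                label=meta.get("label", path.stem), band=band)
    with h5py.File(path, "r") as h5:
        names = list(h5.keys())
        if not names:
            raise ValidationError(f"{path}: empty container")
        name = channel or names[0]
        g = h5[name]
        return ContinuousSignal(g["samples"][()], fs=float(g.attrs["fs"]),
                                t_start=float(g.attrs["t_start"]), label=name,
                                band=tuple(g.attrs["band"]))


# ----------------------------------------------------------------- spikes

def write_spikes(trains: list[SpikeTrain], path: str | Path) -> None:
    rows = [(tr.unit_id, t) for tr in trains for t in tr.times]
    df = pd.DataFrame(rows, columns=["unit_id", "time_s"])
    with open(path, "w") as fh:
        spans = ";".join(f"{tr.unit_id}:{tr.span[0]!r}:{tr.span[1]!r}" for tr in trains)
        fh.write(f"# spans={spans}\n")
        df.to_csv(fh, index=False)


def read_spikes(path: str | Path, strict: bool = False) -> list[SpikeTrain]:
    """Read a (unit_id, time_s) spike table into one train per unit.

    Unit order follows first appearance in the file.  Unsorted times within a
    unit are sorted with a warning, or rejected in strict mode; duplicate
    timestamps within a unit are always an error in strict mode.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spans: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for entry in first[1:].strip().removeprefix("spans=").split(";"):
                if entry:
                    uid, a, b = entry.rsplit(":", 2)
                    spans[uid] = (float(a), float(b))
            body = fh.read()
        else:
            body = first + fh.read()
    from io import StringIO
    df = pd.read_csv(StringIO(body)) if body.strip() else pd.DataFrame(
        columns=["unit_id", "time_s"])
    trains = []
    for uid in df["unit_id"].astype(str).drop_duplicates():
        times = df.loc[df["unit_id"].astype(str) == uid, "time_s"].to_numpy(float)
        if times.size and np.any(np.diff(times) < 0):
            if strict:
                raise ValidationError(f"unit {uid}: unsorted spike times")
            warnings.warn(f"unit {uid}: unsorted spike times; sorting")
            times = np.sort(times)
        if times.size and np.any(np.diff(times) == 0):
            if strict:
                raise ValidationError(f"unit {uid}: duplicate spike timestamps")
            warnings.warn(f"unit {uid}: duplicate timestamps; de-duplicating")
            times = np.unique(times)
        span = spans.get(uid, (min(0.0, times.min() if times.size else 0.0),
                               (times.max() + 1.0) if times.size else 1.0))
        trains.append(SpikeTrain(uid, times, span))
    return trains


# --------------------------------------------------------------- protocol

def write_protocol(protocol: StimProtocol, path: str | Path) -> None:
    event = np.repeat(np.arange(protocol.n_events), protocol.pulses_per_event)
    df = pd.DataFrame({"pulse_time_s": protocol.pulse_times, "event": event})
    with open(path, "w") as fh:
        fh.write(f"# pattern={protocol.pattern} intensity={protocol.intensity!r} "
                 f"pulses_per_event={protocol.pulses_per_event} "
                 f"intra_event_interval={protocol.intra_event_interval!r}\n")
        df.to_csv(fh, index=False)


def read_protocol(path: str | Path) -> StimProtocol:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, v = tok.split("=", 1)
                meta[k] = v
            body = fh.read()
        else:
            body = first + fh.read()
    from io import StringIO
    df = pd.read_csv(StringIO(body))
    ppe = int(meta["pulses_per_event"])
    pulses = df["pulse_time_s"].to_numpy(float)
    onsets = pulses.reshape(-1, ppe)[:, 0]
    return StimProtocol(pulses, onsets, float(meta["intensity"]), meta["pattern"],
                        ppe, float(meta["intra_event_interval"]))


# ------------------------------------------------------------ speed/epochs

def write_speed(speed: SpeedTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": speed.times, "speed": speed.speed})
    with open(path, "w") as fh:
        fh.write(f"# fs_video={speed.fs_video!r}\n")
        df.to_csv(fh, index=False)


def read_speed(path: str | Path) -> SpeedTrace:
    with open(path) as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("#"):
            for tok in first[1:].split():
                k, v = tok.split("=", 1)
                meta[k] = v
            body = fh.read()
        else:
            body = first + fh.read()
    from io import StringIO
    df = pd.read_csv(StringIO(body))
    return SpeedTrace(df["time_s"].to_numpy(float), df["speed"].to_numpy(float),
                      fs_video=float(meta.get("fs_video", 25.0)))


def write_epochs(epochs: dict[str, EpochSet] | EpochSet, path: str | Path) -> None:
    if isinstance(epochs, EpochSet):
        epochs = {epochs.state_label or "state": epochs}
    rows = [(label, t0, t1) for label, es in epochs.items() for t0, t1 in es]
    pd.DataFrame(rows, columns=["state", "t0", "t1"]).to_csv(path, index=False)


def read_epochs(path: str | Path) -> dict[str, EpochSet]:
    df = pd.read_csv(path)
    out = {}
    for label, grp in df.groupby("state", sort=False):
        out[str(label)] = EpochSet(grp[["t0", "t1"]].to_numpy(float), str(label))
    return out


# ------------------------------------------------------------- validation

@dataclass
class AlignmentReport:
    status: str                 # "ok" | "no events" | "pulses outside span"
    n_outside: int
    min_pre_margin: float | None
    min_post_margin: float | None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def validate_alignment(signal: ContinuousSignal, protocol: StimProtocol) -> AlignmentReport:
    """Report-only check that stimulation events fall inside the signal span."""
    if protocol.n_events == 0:
        return AlignmentReport("no events", 0, None, None)
    p = protocol.pulse_times
    outside = int(np.sum((p < signal.t_start) | (p >= signal.t_end)))
    pre = float(protocol.train_onsets.min() - signal.t_start)
    post = float(signal.t_end - protocol.event_final_pulses().max())
    status = "ok" if outside == 0 else "pulses outside span"
    return AlignmentReport(status, outside, pre, post)
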