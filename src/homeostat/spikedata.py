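"""Spike-train data model and I/O.

Sorted spike times from multi-electrode array (MEA) recordings are the
universal input of the analysis stages: per-unit trains, recording
sessions with labeled epochs, and the time segments (e.g. the first
20 min of each hour) on which every downstream metric is computed.

Conventions: all times in seconds, 0-based; every interval is half-open
[start, end); spike times are kept at 0.1-ms resolution (10-kHz
acquisition), duplicates at that resolution are collapsed with a warning.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

#: spike-time resolution, seconds (10-kHz sampling)
TIME_RESOLUTION = 1e-4


@dataclass(frozen=True)
class TimeSegment:
    """Half-open time interval [start, end), seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"segment end ({self.end}) must exceed start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: np.ndarray | float) -> np.ndarray | bool:
        return (np.asarray(t) >= self.start) & (np.asarray(t) < self.end)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one unit within a validity interval.

    ``times`` are strictly increasing at 0.1-ms resolution; an empty
    train is legal.  ``is_multiunit`` tags unresolved multi-neuron
    clusters, which flow through identical code paths but are reported
    separately.
    """

    unit_id: str
    times: np.ndarray
    valid_interval: TimeSegment
    is_multiunit: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D sequence")
        if t.size and not np.all(np.isfinite(t)):
            raise ValueError(f"unit {self.unit_id!r}: non-finite spike times")
        t = np.sort(t)
        # collapse duplicates at the acquisition resolution
        if t.size > 1:
            quant = np.round(t / TIME_RESOLUTION).astype(np.int64)
            keep = np.concatenate([[True], np.diff(quant) > 0])
            if not keep.all():
                warnings.warn(
                    f"unit {self.unit_id!r}: collapsed {int((~keep).sum())} "
                    f"duplicate spike(s) at {TIME_RESOLUTION * 1e3:g}-ms resolution",
                    stacklevel=2,
                )
                t = t[keep]
        if t.size:
            lo, hi = self.valid_interval.start, self.valid_interval.end
            if t[0] < lo or t[-1] >= hi:
                raise ValueError(
                    f"unit {self.unit_id!r}: spike times outside valid interval "
                    f"[{lo}, {hi})"
                )
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class RecordingSession:
    """A set of sorted units recorded simultaneously, with labeled epochs.

    ``epochs`` maps a condition label (e.g. ``baseline``, ``baclofen``)
    to a :class:`TimeSegment`; epochs must be disjoint and lie within
    ``[0, duration)``.
    """

    trains: dict[str, SpikeTrain]
    duration: float
    epochs: dict[str, TimeSegment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        segs = sorted(self.epochs.values(), key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError("epochs overlap")
        for seg in segs:
            if seg.start < 0 or seg.end > self.duration + TIME_RESOLUTION:
                raise ValueError("epoch outside [0, duration)")

    @property
    def unit_ids(self) -> list[str]:
        return list(self.trains)

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def total_spikes(self) -> int:
        return sum(tr.n_spikes for tr in self.trains.values())


# ---------------------------------------------------------------------------
# I/O: delimited text and HDF5
# ---------------------------------------------------------------------------

def _session_from_frame(df: pd.DataFrame, duration: float | None) -> RecordingSession:
    if not {"unit_id", "time_s"}.issubset(df.columns):
        raise ValueError("spike table must have columns 'unit_id' and 'time_s'")
    times = df["time_s"].to_numpy(dtype=np.float64)
    if times.size and (not np.all(np.isfinite(times)) or times.min() < 0):
        raise ValueError("spike times must be finite and non-negative")
    if duration is None:
        if times.size:
            # round up to the next whole second, keeping the last spike
            # strictly inside the half-open [0, duration) interval
            duration = float(math.floor(times.max()) + 1)
        else:
            duration = 0.0
    interval = TimeSegment(0.0, max(duration, TIME_RESOLUTION))
    trains = {
        str(uid): SpikeTrain(str(uid), grp["time_s"].to_numpy(np.float64), interval)
        for uid, grp in df.groupby("unit_id", sort=True)
    }
    return RecordingSession(trains=trains, duration=duration)


def read_spike_table(path: str | Path, dialect: str | None = None) -> RecordingSession:
    """Read a spike table (CSV with header ``unit_id,time_s``, or HDF5).

    HDF5 layout: one dataset of times per unit under ``/units/<id>``; the
    file attribute ``duration`` overrides the ceil-of-last-spike default.
    A JSON sidecar ``<path>.epochs.json`` supplies epoch labels if present.
    """
    path = Path(path)
    if dialect is None:
        dialect = "hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "csv"
    if dialect == "csv":
        df = pd.read_csv(path)
        session = _session_from_frame(df, duration=None)
    elif dialect == "hdf5":
        with h5py.File(path, "r") as f:
            duration = float(f.attrs["duration"]) if "duration" in f.attrs else None
            rows = []
            for uid in f["units"]:
                t = f["units"][uid][...]
                rows.append(pd.DataFrame({"unit_id": uid, "time_s": t}))
            df = (
                pd.concat(rows, ignore_index=True)
                if rows
                else pd.DataFrame(columns=["unit_id", "time_s"])
            )
        session = _session_from_frame(df, duration=duration)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    sidecar = path.with_suffix(path.suffix + ".epochs.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        session.epochs = {
            k: TimeSegment(v[0], v[1]) for k, v in meta.get("epochs", {}).items()
        }
        if "duration" in meta:
            session.duration = float(meta["duration"])
    return session


def write_spike_table(session: RecordingSession, path: str | Path,
                      dialect: str | None = None) -> None:
    """Write a session in the same formats :func:`read_spike_table` reads."""
    path = Path(path)
    if dialect is None:
        dialect = "hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "csv"
    if dialect == "csv":
        rows = [
            pd.DataFrame({"unit_id": uid, "time_s": tr.times})
            for uid, tr in session.trains.items()
        ]
        df = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(columns=["unit_id", "time_s"])
        )
        df.to_csv(path, index=False, float_format="%.4f")
    elif dialect == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["duration"] = session.duration
            g = f.create_group("units")
            for uid, tr in session.trains.items():
                g.create_dataset(str(uid), data=tr.times)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if session.epochs:
        sidecar = path.with_suffix(path.suffix + ".epochs.json")
        sidecar.write_text(json.dumps({
            "duration": session.duration,
            "epochs": {k: [s.start, s.end] for k, s in session.epochs.items()},
        }))


# ---------------------------------------------------------------------------
# Segmentation and rates
# ---------------------------------------------------------------------------

def hourly_segments(session: RecordingSession, window_min: float = 20.0
                    ) -> list[TimeSegment]:
    """The first ``window_min`` minutes of each complete hour of the session.

    Incomplete trailing hours are dropped.  Using a 20-min window per hour
    is the standard down-sampling for long MEA recordings; it represents
    the full-hour mean firing rate accurately (see the
    segment-representativeness analysis in :mod:`homeostat.stability`).
    """
    if window_min > 60:
        raise ValueError("window_min must be <= 60")
    n_hours = int(session.duration // 3600)
    return [
        TimeSegment(h * 3600.0, h * 3600.0 + window_min * 60.0)
        for h in range(n_hours)
    ]


def restrict(train: SpikeTrain, seg: TimeSegment) -> SpikeTrain:
    """Spikes of ``train`` falling in ``[seg.start, seg.end)``."""
    lo = np.searchsorted(train.times, seg.start, side="left")
    hi = np.searchsorted(train.times, seg.end, side="left")
    return SpikeTrain(train.unit_id, train.times[lo:hi], seg,
                      is_multiunit=train.is_multiunit)


def mean_firing_rate(train: SpikeTrain, seg: TimeSegment) -> float:
    """Spike count in ``seg`` divided by its duration, Hz."""
    if seg.duration <= 0:
        raise ValueError("segment duration must be positive")
    lo = np.searchsorted(train.times, seg.start, side="left")
    hi = np.searchsorted(train.times, seg.end, side="left")
    return (hi - lo) / seg.duration


def population_mfr(session: RecordingSession, seg: TimeSegment,
                   unit_ids: Iterable[str] | None = None) -> float:
    """Population mean firing rate: mean over units of per-unit MFR."""
    ids = list(unit_ids) if unit_ids is not None else session.unit_ids
    if not ids:
        return float("nan")
    return float(np.mean([mean_firing_rate(session.trains[u], seg) for u in ids]))
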