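"""Raw accelerometer recordings, direct-observation event logs, and their alignment.

Two plain-text formats are supported, both comma-separated with one header row
and ISO-8601 timestamps at millisecond precision:

* Recording CSV: columns ``timestamp,x,y,z`` — one row per sample, acceleration
  in g units.
* Event-log CSV: columns ``start,end,code`` (optionally ``subject_id``) — one
  row per observed movement event.

The five activity classes form a closed, ordered label set; the observation
scheme additionally codes intervals where the child left the camera frame as
``OUT_OF_VIEW``.  Samples that fall in a gap between events receive the
sentinel ``UNLABELED``, which is distinct from ``OUT_OF_VIEW``: the former
means "nobody coded this time", the latter "it was coded as unobservable".
Both are excluded from model training downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, UsageError

#: Closed, ordered activity-class label set. The order is fixed and is used
#: for every confusion matrix and report in the package.
ACTIVITY_CLASSES: tuple[str, ...] = ("SED", "LIGHT_AG", "MV_AG", "WALK", "RUN")

#: Code for intervals where the subject could not be observed.
OUT_OF_VIEW = "OUT_OF_VIEW"

#: All codes an event log may contain.
EVENT_CODES: tuple[str, ...] = ACTIVITY_CLASSES + (OUT_OF_VIEW,)

#: Sentinel for samples not covered by any event.
UNLABELED = "UNLABELED"

#: Window label for windows without a usable strict-majority class.
EXCLUDED = "EXCLUDED"

PLACEMENTS = ("hip", "wrist")

# Integer encoding used for per-sample label arrays (int8-friendly).
CODE_TO_INT = {code: i for i, code in enumerate(EVENT_CODES)}
INT_TO_CODE = {i: code for code, i in CODE_TO_INT.items()}
UNLABELED_INT = -1


class Event(NamedTuple):
    start: pd.Timestamp
    end: pd.Timestamp
    code: str


@dataclass
class Recording:
    """One subject x placement tri-axial acceleration stream.

    ``samples`` is an (N, 3) float array of (ax, ay, az) in g; samples are
    uniformly spaced at ``sample_rate_hz`` starting at ``start_time``.
    """

    subject_id: str
    placement: str
    sample_rate_hz: float
    start_time: pd.Timestamp
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise UsageError("samples must be an (N, 3) array")
        if self.samples.shape[0] < 1:
            raise IntegrityError("a recording needs at least one sample")
        if not self.sample_rate_hz > 0:
            raise UsageError("sample_rate_hz must be positive")
        if self.placement not in PLACEMENTS:
            raise UsageError(f"placement must be one of {PLACEMENTS}")
        if not np.isfinite(self.samples).all():
            raise IntegrityError("recording contains non-finite acceleration values")
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def sample_times_ns(self) -> np.ndarray:
        """Epoch nanoseconds of every sample (uniform grid)."""
        step_ns = 1e9 / self.sample_rate_hz
        base = self.start_time.value
        return base + np.round(np.arange(self.n_samples) * step_ns).astype(np.int64)

    def sample_times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.sample_times_ns())


@dataclass
class EventLog:
    """Ordered, non-overlapping labeled intervals of observed behavior."""

    subject_id: str
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        events = [Event(pd.Timestamp(s), pd.Timestamp(e), c) for s, e, c in self.events]
        events.sort(key=lambda ev: ev.start)
        for ev in events:
            if ev.code not in EVENT_CODES:
                raise FormatError(f"unknown activity code {ev.code!r}")
            if not ev.start < ev.end:
                raise IntegrityError(f"event has start >= end: {ev}")
        for a, b in zip(events, events[1:]):
            if b.start < a.end:
                raise IntegrityError(f"overlapping events: {a} / {b}")
        self.events = events

    def __len__(self) -> int:
        return len(self.events)

    def starts_ns(self) -> np.ndarray:
        return np.array([ev.start.value for ev in self.events], dtype=np.int64)

    def ends_ns(self) -> np.ndarray:
        return np.array([ev.end.value for ev in self.events], dtype=np.int64)

    def codes_int(self) -> np.ndarray:
        return np.array([CODE_TO_INT[ev.code] for ev in self.events], dtype=np.int8)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_REC_COLUMNS = ("timestamp", "x", "y", "z")


def read_recording(path, placement: str, sample_rate_hz: float,
                   subject_id: str | None = None) -> Recording:
    """Read a recording CSV (columns ``timestamp,x,y,z``).

    The nominal ``sample_rate_hz`` is taken as authoritative; timestamps are
    checked for strict monotonicity only.  ``subject_id`` defaults to the
    file stem.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    ts = pd.to_datetime(df["timestamp"]).to_numpy()
    if len(ts) > 1 and not (np.diff(ts.astype("int64")) > 0).all():
        raise IntegrityError(f"{path}: timestamps are not strictly increasing")
    samples = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.isfinite(samples).all():
        raise IntegrityError(f"{path}: non-finite acceleration value")
    if subject_id is None:
        import os

        subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    return Recording(
        subject_id=subject_id,
        placement=placement,
        sample_rate_hz=sample_rate_hz,
        start_time=pd.Timestamp(ts[0]),
        samples=samples,
    )


def write_recording(rec: Recording, path) -> None:
    """Write a recording to CSV with millisecond ISO-8601 timestamps."""
    times = rec.sample_times().round("ms")
    df = pd.DataFrame(
        {
            "timestamp": times.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3],
            "x": rec.samples[:, 0],
            "y": rec.samples[:, 1],
            "z": rec.samples[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_eventlog(path, subject_id: str | None = None) -> EventLog:
    """Read an event-log CSV (columns ``start,end,code``); validates codes,
    ordering and non-overlap."""
    df = pd.read_csv(path)
    missing = [c for c in ("start", "end", "code") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    bad = set(df["code"]) - set(EVENT_CODES)
    if bad:
        raise FormatError(f"{path}: unknown activity code(s) {sorted(bad)}")
    if subject_id is None:
        if "subject_id" in df.columns:
            ids = df["subject_id"].unique()
            if len(ids) != 1:
                raise FormatError(f"{path}: multiple subject ids {list(ids)}")
            subject_id = str(ids[0])
        else:
            import os

            subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    events = [
        Event(pd.Timestamp(s), pd.Timestamp(e), c)
        for s, e, c in zip(pd.to_datetime(df["start"]), pd.to_datetime(df["end"]), df["code"])
    ]
    return EventLog(subject_id=subject_id, events=events)


def write_eventlog(log: EventLog, path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": log.subject_id,
            "start": [ev.start.round("ms").strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] for ev in log.events],
            "end": [ev.end.round("ms").strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] for ev in log.events],
            "code": [ev.code for ev in log.events],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_samples(rec: Recording, log: EventLog) -> np.ndarray:
    """Assign each sample the code of the event containing its timestamp.

    Event intervals are half-open ``[start, end)`` so boundary samples are
    never double-labeled.  Returns an int8 array of length N: values are
    indices into :data:`EVENT_CODES`, or :data:`UNLABELED_INT` (-1) for
    samples outside every event.
    """
    if rec.subject_id != log.subject_id:
        raise UsageError(
            f"subject mismatch: recording {rec.subject_id!r} vs log {log.subject_id!r}"
        )
    t = rec.sample_times_ns()
    labels = np.full(rec.n_samples, UNLABELED_INT, dtype=np.int8)
    if len(log) == 0:
        return labels
    starts, ends, codes = log.starts_ns(), log.ends_ns(), log.codes_int()
    idx = np.searchsorted(starts, t, side="right") - 1
    valid = idx >= 0
    inside = np.zeros_like(valid)
    inside[valid] = t[valid] < ends[idx[valid]]
    labels[inside] = codes[idx[inside]]
    return labels


def decode_labels(labels: Iterable[int]) -> list[str]:
    """Map an integer label array back to code strings."""
    return [INT_TO_CODE.get(int(v), UNLABELED) for v in labels]
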