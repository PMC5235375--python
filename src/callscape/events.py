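"""Turn per-frame decisions into timestamped call events.

Two smoothing rules: short gaps inside a call are closed (fragment
repair), and calls separated by at most the merge gap are joined into a
single call-series event.  Events shorter than the minimum call duration
are discarded after fragment repair.  An event's end extends to the end
of the last positive frame's analysis window, so a single positive frame
has nonzero duration.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "DetectionEvent",
    "smooth",
    "to_absolute",
    "parse_recording_start",
    "events_to_frame",
    "write_events_csv",
    "read_events_csv",
]

#: Song-Meter-style filename: <station>_<YYYYMMDD>_<HHMMSS>.wav
FILENAME_PATTERN = r"^(?P<station>.+)_(?P<date>\d{8})_(?P<time>\d{6})\.(wav|WAV)$"


@dataclass(frozen=True)
class DetectionEvent:
    """One machine-detected call event (isolated call or call series)."""

    start_s: float
    end_s: float
    mean_llr: float = float("nan")
    recording_id: str = ""
    absolute_start: dt.datetime | None = None

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("event end must be after its start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _runs(decisions: np.ndarray) -> list[tuple[int, int]]:
    """Positive runs as (first_frame, last_frame) inclusive."""
    d = np.asarray(decisions, dtype=bool).astype(np.int8)
    if d.size == 0:
        return []
    edges = np.diff(np.concatenate([[0], d, [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _join_close(spans: list[tuple[float, float]], max_gap_s: float) -> list[tuple[float, float]]:
    joined: list[tuple[float, float]] = []
    for s, e in spans:
        if joined and s - joined[-1][1] <= max_gap_s:
            joined[-1] = (joined[-1][0], max(joined[-1][1], e))
        else:
            joined.append((s, e))
    return joined


def smooth(
    decisions,
    hop_s: float = 0.005,
    window_s: float = 0.020,
    close_gap_s: float = 0.05,
    min_call_s: float = 0.05,
    merge_gap_s: float = 0.6,
    llr: np.ndarray | None = None,
    recording_id: str = "",
) -> list[DetectionEvent]:
    """Smooth frame decisions into disjoint, sorted call events.

    Steps: (1) close gaps <= ``close_gap_s`` between positive runs;
    (2) discard repaired calls shorter than ``min_call_s``;
    (3) merge surviving calls separated by <= ``merge_gap_s``.
    Timestamps: start of first frame to start of last frame + ``window_s``.
    """
    spans = [(a * hop_s, b * hop_s + window_s) for a, b in _runs(decisions)]
    spans = _join_close(spans, close_gap_s)
    spans = [(s, e) for s, e in spans if e - s >= min_call_s]
    spans = _join_close(spans, merge_gap_s)
    llr = None if llr is None else np.asarray(llr, dtype=np.float64)
    events = []
    for s, e in spans:
        mean_llr = float("nan")
        if llr is not None:
            lo = int(np.ceil(s / hop_s - 1e-9))
            hi = int(np.floor((e - window_s) / hop_s + 1e-9))
            seg = llr[lo : hi + 1]
            if seg.size:
                mean_llr = float(np.mean(seg))
        events.append(DetectionEvent(s, e, mean_llr, recording_id))
    return events


def parse_recording_start(filename: str, pattern: str = FILENAME_PATTERN) -> dt.datetime:
    """Recording start time encoded in the filename.

    Raises ``ValueError`` naming the expected pattern when the filename
    does not match.
    """
    m = re.match(pattern, filename)
    if m is None:
        raise ValueError(
            f"filename {filename!r} does not match the expected pattern "
            f"<station>_<YYYYMMDD>_<HHMMSS>.wav ({pattern})"
        )
    return dt.datetime.strptime(m.group("date") + m.group("time"), "%Y%m%d%H%M%S")


def to_absolute(events: list[DetectionEvent], recording_start: dt.datetime | str) -> list[DetectionEvent]:
    """Attach absolute timestamps: recording start + in-file offset."""
    if isinstance(recording_start, str):
        recording_start = parse_recording_start(recording_start)
    return [replace(ev, absolute_start=recording_start + dt.timedelta(seconds=ev.start_s))
            for ev in events]


def events_to_frame(events: list[DetectionEvent]) -> pd.DataFrame:
    return pd.DataFrame({
        "recording_id": [ev.recording_id for ev in events],
        "start_s": [ev.start_s for ev in events],
        "end_s": [ev.end_s for ev in events],
        "absolute_start": [
            ev.absolute_start.isoformat() if ev.absolute_start else "" for ev in events
        ],
        "mean_llr": [ev.mean_llr for ev in events],
    })


def write_events_csv(path, events: list[DetectionEvent]) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path) -> list[DetectionEvent]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        absolute = dt.datetime.fromisoformat(row.absolute_start) if row.absolute_start else None
        out.append(DetectionEvent(float(row.start_s), float(row.end_s),
                                  float(row.mean_llr) if row.mean_llr != "" else float("nan"),
                                  str(row.recording_id), absolute))
    return out
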