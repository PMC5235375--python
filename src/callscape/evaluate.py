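"""Detector performance assessment.

Two prongs: (I) precision on a random sample of detections, with a
minimum-size rule; (II) validation-library metrics against exhaustively
annotated recordings — hits, insertions, double hits, exclusion of
unconfirmed events, the four percentage metrics, and cumulative binning
of annotated events by loudest-call amplitude in 5-dB steps.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnnotatedEvent",
    "ValidationSummary",
    "round_half_up",
    "sample_size",
    "draw_sample",
    "match",
    "precision",
    "accuracy",
    "correct",
    "missed",
    "bin_by_db",
]

LABELS = ("target", "unconfirmed", "nontarget")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Matches how the reported percentage tables are rounded (banker's
    rounding would disagree on exact .5 ties).
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class AnnotatedEvent:
    """One expert-annotated sound event with the loudest-call level."""

    start_s: float
    end_s: float
    label: str
    peak_dbfs: float | None = None

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("event end must be after its start")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.label in ("target", "unconfirmed") and self.peak_dbfs is None:
            raise ValueError(f"{self.label} events must carry peak_dbfs")
        if self.peak_dbfs is not None and self.peak_dbfs > 0:
            raise ValueError("peak_dbfs must be <= 0 (dB relative to full scale)")


@dataclass
class ValidationSummary:
    """Tallies of a matching run: hits, insertions, doubles, exclusions."""

    H: int  # hits (true positives)
    I: int  # insertions (false positives)
    N: int  # total confirmed target events in the annotations
    doubles: int = 0
    excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.H, self.I, self.N, self.doubles, self.excluded) < 0:
            raise ValueError("all tallies must be non-negative")
        if self.H > self.N:
            raise ValueError("cannot have more hits than annotated target events")

    @property
    def misses(self) -> int:
        return self.N - self.H


def sample_size(monthly_detections: int, minimum: int = 150, fraction: float = 0.02) -> int:
    """Random-sample size rule: max(minimum, fraction of detections), capped.

    Low-activity months get the fixed minimum; high-activity months get
    the percentage.  Never exceeds the number of detections available.
    """
    if monthly_detections < 0:
        raise ValueError("detection count must be non-negative")
    n = max(minimum, int(round_half_up(fraction * monthly_detections)))
    return min(n, monthly_detections)


def draw_sample(detections: list, n: int, seed: int) -> list:
    """Uniform random subsample without replacement, reproducible per seed."""
    if n > len(detections):
        raise ValueError(f"cannot draw {n} from {len(detections)} detections")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(detections), size=n, replace=False))
    return [detections[i] for i in idx]


def _overlap(a_start: float, a_end: float, b_start: float, b_end: float) -> float:
    return min(a_end, b_end) - max(a_start, b_start)


def match(detections, annotations, min_overlap_frac: float = 0.0) -> ValidationSummary:
    """Match detections against annotations, resolving doubles and exclusions.

    A detection overlapping at least one confirmed target event is a hit
    if it is the first detection to overlap that event, otherwise a
    double hit.  Detections spanning several target events are credited
    to the earliest one.  Detections overlapping only unconfirmed events
    are excluded from the valid sample; everything else is an insertion.
    ``min_overlap_frac`` optionally requires the intersection to cover at
    least that fraction of the detection's duration.
    """
    targets = sorted((a for a in annotations if a.label == "target"), key=lambda a: a.start_s)
    unconfirmed = [a for a in annotations if a.label == "unconfirmed"]
    hit_taken = [False] * len(targets)
    H = I = doubles = excluded = 0
    for det in sorted(detections, key=lambda d: d.start_s):
        dur = det.end_s - det.start_s
        needed = min_overlap_frac * dur

        def overlaps(ann) -> bool:
            ov = _overlap(det.start_s, det.end_s, ann.start_s, ann.end_s)
            return ov > 0 and ov >= needed

        matched = [i for i, t in enumerate(targets) if overlaps(t)]
        if matched:
            first = matched[0]  # earliest overlapped target event
            if hit_taken[first]:
                doubles += 1
            else:
                hit_taken[first] = True
                H += 1
        elif any(overlaps(u) for u in unconfirmed):
            excluded += 1
        else:
            I += 1
    return ValidationSummary(H=H, I=I, N=len(targets), doubles=doubles, excluded=excluded)


def precision(H: int, I: int) -> float:
    """Hits over assessed valid detections, in percent (1 decimal)."""
    if H + I <= 0:
        raise ValueError("precision undefined for an empty valid sample")
    return round_half_up(H / (H + I) * 100.0, 1)


def accuracy(H: int, I: int, N: int) -> float:
    """(H - I) / N in percent (1 decimal); may be negative."""
    if N <= 0:
        raise ValueError("accuracy undefined for N = 0")
    return round_half_up((H - I) / N * 100.0, 1)


def correct(H: int, N: int) -> float:
    """H / N in percent (1 decimal)."""
    if N <= 0:
        raise ValueError("correct undefined for N = 0")
    return round_half_up(H / N * 100.0, 1)


def missed(H: int, N: int) -> float:
    """(N - H) / N in percent (1 decimal)."""
    if N <= 0:
        raise ValueError("missed undefined for N = 0")
    return round_half_up((N - H) / N * 100.0, 1)


def bin_by_db(events, bin_width: float = 5.0) -> pd.DataFrame:
    """Cumulative amplitude table of annotated target/unconfirmed events.

    Events are binned by loudest-call level in ``bin_width``-dB steps
    (bin k spans ``(-(k+1)w, -kw]``); each row reports the cumulative
    0-to--X counts and percentage unconfirmed (1 decimal; NA when the
    cumulative total is zero).  A final row covers the full range down to
    -infinity.
    """
    kept = [e for e in events if e.label in ("target", "unconfirmed")]
    for e in kept:
        if e.peak_dbfs is None:
            raise ValueError("all binned events must carry peak_dbfs")
        if e.peak_dbfs > 0:
            raise ValueError("positive dBFS peak is invalid")
    if kept:
        deepest = min(e.peak_dbfs for e in kept)
        n_bins = max(1, int(np.ceil(-deepest / bin_width)))
    else:
        n_bins = 1
    tgt = np.zeros(n_bins + 1, dtype=int)  # last slot: overflow to -inf
    unc = np.zeros(n_bins + 1, dtype=int)
    for e in kept:
        k = min(int(np.floor(-e.peak_dbfs / bin_width - 1e-12)), n_bins - 1) if e.peak_dbfs < 0 else 0
        (tgt if e.label == "target" else unc)[k] += 1
    rows = []
    cum_t = cum_u = 0
    for k in range(n_bins + 1):
        cum_t += int(tgt[k])
        cum_u += int(unc[k])
        lower = -(k + 1) * bin_width if k < n_bins else -np.inf
        total = cum_t + cum_u
        pct = round_half_up(cum_u / total * 100.0, 1) if total else np.nan
        rows.append({
            "range_db": f"0 to {lower:g}" if np.isfinite(lower) else "0 to -inf",
            "lower_db": lower,
            "n_target": int(tgt[k]),
            "n_unconfirmed": int(unc[k]),
            "cum_target": cum_t,
            "cum_unconfirmed": cum_u,
            "cum_total": total,
            "pct_unconfirmed": pct,
        })
    return pd.DataFrame(rows)
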