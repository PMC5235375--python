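"""Vocal-activity phenology: false-positive correction, diel profiles, tests.

Raw per-period day/night detection counts are corrected by the precision
estimated from each period's random verdict sample; daily series and
clock-binned diel profiles are built from timestamped events; a
one-tailed Spearman test relates water level to activity, and a one-way
ANOVA with Tukey HSD compares nightly counts grouped by lunar phase.
"""

from __future__ import annotations

import datetime as dt
import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .evaluate import round_half_up
from .solar import SYNODIC_MONTH_DAYS, SolarContext, nearest_phase_date

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityPeriod",
    "LunarGroups",
    "AnovaResult",
    "classify_day_night",
    "period_precision",
    "correct_counts",
    "activity_table",
    "daily_series",
    "diel_profile",
    "spearman_one_tailed",
    "lunar_groups",
    "lunar_anova",
]

# Day window relative to sun events: one hour before sunrise to 45 min
# after sunset, both ends inclusive.
DAY_START_BEFORE_SUNRISE = dt.timedelta(hours=1)
DAY_END_AFTER_SUNSET = dt.timedelta(minutes=45)


@dataclass
class ActivityPeriod:
    """One acoustic activity period: raw counts plus sampled verdicts."""

    id: int | str
    start_date: dt.date
    end_date: dt.date  # inclusive
    raw_day: int
    raw_night: int
    n_correct: int
    n_false: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("period end date precedes start date")
        if min(self.raw_day, self.raw_night, self.n_correct, self.n_false, self.n_excluded) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def raw_total(self) -> int:
        return self.raw_day + self.raw_night

    @property
    def n_sampled(self) -> int:
        return self.n_correct + self.n_false + self.n_excluded

    @property
    def n_valid(self) -> int:
        return self.n_correct + self.n_false

    @property
    def precision_fraction(self) -> float:
        if self.n_valid == 0:
            raise ValueError("precision undefined: no valid sampled verdicts")
        return self.n_correct / self.n_valid

    def contains(self, date: dt.date) -> bool:
        return self.start_date <= date <= self.end_date


def classify_day_night(event_time: dt.datetime, solar: SolarContext) -> str:
    """'day' iff the event falls between sunrise - 1 h and sunset + 45 min."""
    sunrise, sunset = solar.sun_times(event_time.date())
    if sunrise - DAY_START_BEFORE_SUNRISE <= event_time <= sunset + DAY_END_AFTER_SUNSET:
        return "day"
    return "night"


def period_precision(period: ActivityPeriod) -> float:
    """Sampled precision of the period, in percent (1 decimal)."""
    return round_half_up(period.precision_fraction * 100.0, 1)


def correct_counts(period: ActivityPeriod) -> tuple[float, float]:
    """Corrected (day, night) counts: raw times the precision fraction.

    Returned unrounded; round only at display time.  Totals over several
    periods must sum the unrounded values before rounding.
    """
    p = period.precision_fraction
    return period.raw_day * p, period.raw_night * p


def activity_table(periods: list[ActivityPeriod]) -> pd.DataFrame:
    """Per-period report with a total column (corrected cells rounded half-up).

    The total row of corrected counts is the rounded sum of unrounded
    per-period values, and the total precision is computed from pooled
    verdict counts.
    """
    if not periods:
        raise ValueError("need at least one period")
    cols = {}
    corr = [correct_counts(p) for p in periods]
    for p, (cd, cn) in zip(periods, corr):
        cols[str(p.id)] = {
            "date_range": f"{p.start_date:%m%d}-{p.end_date:%m%d}",
            "raw_day": p.raw_day,
            "raw_night": p.raw_night,
            "raw_total": p.raw_total,
            "n_sampled": p.n_sampled,
            "pct_of_total": round_half_up(p.n_sampled / p.raw_total * 100.0, 1),
            "n_correct": p.n_correct,
            "n_false": p.n_false,
            "n_excluded": p.n_excluded,
            "n_valid": p.n_valid,
            "precision_pct": period_precision(p),
            "corrected_day": int(round_half_up(cd)),
            "corrected_night": int(round_half_up(cn)),
            "corrected_total": int(round_half_up(cd + cn)),
        }
    tot_correct = sum(p.n_correct for p in periods)
    tot_valid = sum(p.n_valid for p in periods)
    tot_raw = sum(p.raw_total for p in periods)
    tot_sampled = sum(p.n_sampled for p in periods)
    cols["total"] = {
        "date_range": f"{periods[0].start_date:%m%d}-{periods[-1].end_date:%m%d}",
        "raw_day": sum(p.raw_day for p in periods),
        "raw_night": sum(p.raw_night for p in periods),
        "raw_total": tot_raw,
        "n_sampled": tot_sampled,
        "pct_of_total": round_half_up(tot_sampled / tot_raw * 100.0, 1),
        "n_correct": tot_correct,
        "n_false": sum(p.n_false for p in periods),
        "n_excluded": sum(p.n_excluded for p in periods),
        "n_valid": tot_valid,
        "precision_pct": round_half_up(tot_correct / tot_valid * 100.0, 1),
        "corrected_day": int(round_half_up(sum(cd for cd, _ in corr))),
        "corrected_night": int(round_half_up(sum(cn for _, cn in corr))),
        "corrected_total": int(round_half_up(sum(cd + cn for cd, cn in corr))),
    }
    return pd.DataFrame(cols)


def _owning_period(date: dt.date, periods: list[ActivityPeriod]) -> ActivityPeriod:
    owners = [p for p in periods if p.contains(date)]
    if not owners:
        covered = ", ".join(f"{p.start_date}..{p.end_date}" for p in periods)
        raise ValueError(f"date {date} falls outside all periods (covered: {covered})")
    return owners[0]


def daily_series(daily_counts: pd.DataFrame, periods: list[ActivityPeriod]) -> pd.DataFrame:
    """Scale per-date raw day/night counts by the owning period's precision.

    ``daily_counts`` needs columns ``date``, ``raw_day``, ``raw_night``.
    Dates on a period boundary belong to the period whose inclusive range
    contains them.
    """
    rows = []
    for row in daily_counts.itertuples(index=False):
        date = row.date if isinstance(row.date, dt.date) else pd.Timestamp(row.date).date()
        p = _owning_period(date, periods).precision_fraction
        rows.append({"date": date, "corrected_day": row.raw_day * p,
                     "corrected_night": row.raw_night * p})
    return pd.DataFrame(rows)


def estimate_step_date(daily_counts: pd.Series, smooth_days: int = 5) -> dt.date:
    """Date of the largest single-day jump in smoothed daily counts.

    Descriptive heuristic for locating a sustained step (e.g. the onset of
    peak activity) in a daily series: counts are smoothed with a centred
    ``smooth_days`` rolling mean and the date with the largest positive
    day-to-day increase of the smoothed series is returned.
    """
    if len(daily_counts) < smooth_days + 1:
        raise ValueError("series too short for the smoothing window")
    smoothed = daily_counts.sort_index().rolling(smooth_days, center=True,
                                                 min_periods=1).mean()
    jumps = smoothed.diff().dropna()
    # a clean step yields a plateau of equal jumps; report its midpoint
    ties = jumps.index[jumps >= jumps.max() - 1e-9 * max(abs(jumps.max()), 1.0)]
    return ties[len(ties) // 2]


def diel_profile(timestamps, resolution: str = "quarter_hour",
                 normalize: bool = False) -> pd.Series:
    """Histogram of events over the 24-h clock.

    ``resolution`` is ``"hour"`` (24 bins) or ``"quarter_hour"`` (96).
    With ``normalize`` each bin is expressed as percent of the maximum
    bin, so the busiest bin reads exactly 100.
    """
    if resolution not in ("hour", "quarter_hour"):
        raise ValueError("resolution must be 'hour' or 'quarter_hour'")
    n_bins = 24 if resolution == "hour" else 96
    per_hour = n_bins / 24.0
    counts = np.zeros(n_bins)
    for t in timestamps:
        t = pd.Timestamp(t)
        h = t.hour + t.minute / 60.0 + t.second / 3600.0
        counts[min(int(h * per_hour), n_bins - 1)] += 1
    if normalize and counts.max() > 0:
        counts = counts / counts.max() * 100.0
    return pd.Series(counts, index=range(n_bins), name=resolution)


def spearman_one_tailed(water_cm, activity, alternative: str = "less",
                        method: str = "auto") -> tuple[float, float]:
    """Spearman rank correlation with a one-tailed p-value.

    ``alternative='less'`` tests for a negative association.  The null
    distribution is the exact permutation distribution for n <= 10
    (``method='auto'``/'exact'), otherwise a t approximation.  Ties get
    average ranks.
    """
    x = np.asarray(water_cm, dtype=np.float64)
    y = np.asarray(activity, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    if method == "exact" or (method == "auto" and n <= 10):
        p = _exact_spearman_p(rx, ry, rho, alternative)
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = sps.t.cdf(t, df=n - 2) if alternative == "less" else sps.t.sf(t, df=n - 2)
    return rho, float(p)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float, alternative: str) -> float:
    """Permutation p-value by enumerating all n! pairings of the ranks."""
    n = len(rx)
    xc = rx - rx.mean()
    yc = ry - ry.mean()
    denom = math.sqrt(float(np.sum(xc**2) * np.sum(yc**2)))
    s_obs = rho_obs * denom
    count = 0
    total = 0
    perm_iter = itertools.permutations(range(n))
    chunk_size = 200_000
    tol = 1e-9 * max(1.0, abs(s_obs))
    while True:
        chunk = list(itertools.islice(perm_iter, chunk_size))
        if not chunk:
            break
        idx = np.array(chunk, dtype=np.int8)
        s = yc[idx] @ xc
        if alternative == "less":
            count += int(np.sum(s <= s_obs + tol))
        else:
            count += int(np.sum(s >= s_obs - tol))
        total += len(chunk)
    return count / total


@dataclass
class LunarGroups:
    """Nightly samples around two new moons and the intervening full moon."""

    new_a: list[dt.date]
    full: list[dt.date]
    new_b: list[dt.date]

    def as_dict(self) -> dict[str, list[dt.date]]:
        return {"new_A": self.new_a, "full": self.full, "new_B": self.new_b}


def lunar_groups(dates, nights_per_group: int = 13,
                 phase_dates: dict[str, dt.date] | None = None) -> LunarGroups:
    """Group nights around a full moon and its flanking new moons.

    Each group is ``nights_per_group`` consecutive nights centred on the
    phase date; nights near the quarter moons fall in none of the groups,
    keeping the groups disjoint.  Phase dates come from the synodic
    approximation unless supplied explicitly via ``phase_dates``
    (keys ``new_A``, ``full``, ``new_B``).
    """
    dates = sorted(dates)
    if not dates:
        raise ValueError("no dates supplied")
    available = set(dates)
    if phase_dates is None:
        mid = dates[len(dates) // 2]
        full_date = nearest_phase_date(mid, "full")
        half = dt.timedelta(days=round(SYNODIC_MONTH_DAYS / 2))
        phase_dates = {
            "new_A": nearest_phase_date(full_date - half, "new"),
            "full": full_date,
            "new_B": nearest_phase_date(full_date + half, "new"),
        }
    reach = nights_per_group // 2
    groups = {}
    for key in ("new_A", "full", "new_B"):
        center = phase_dates[key]
        nights = [center + dt.timedelta(days=o) for o in range(-reach, reach + 1)]
        missing = [d for d in nights if d not in available]
        if missing:
            raise ValueError(
                f"insufficient nights for group {key}: missing {missing[:3]}..."
                if len(missing) > 3 else
                f"insufficient nights for group {key}: missing {missing}"
            )
        groups[key] = nights
    lg = LunarGroups(groups["new_A"], groups["full"], groups["new_B"])
    all_nights = lg.new_a + lg.full + lg.new_b
    if len(set(all_nights)) != len(all_nights):
        raise ValueError("lunar groups overlap; supply explicit phase_dates")
    return lg


@dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    tukey: pd.DataFrame
    group_means: dict[str, float]


def lunar_anova(groups: dict[str, np.ndarray], alpha: float = 0.01) -> AnovaResult:
    """One-way ANOVA on log10(count + 1) with Tukey HSD post hoc.

    ``groups`` maps label -> nightly counts.  The +1 offset keeps
    zero-count nights finite.  Tukey p-values use the studentized-range
    distribution; ``significant`` flags pairs at the given alpha.
    """
    labels = list(groups)
    data = [np.log10(np.asarray(groups[g], dtype=np.float64) + 1.0) for g in labels]
    if any(len(d) == 0 for d in data):
        raise ValueError("all groups must be nonempty")
    k = len(data)
    ns = [len(d) for d in data]
    n_total = sum(ns)
    grand = np.concatenate(data).mean()
    ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in data)
    ss_within = sum(np.sum((d - d.mean()) ** 2) for d in data)
    df_b, df_w = k - 1, n_total - k
    if ss_within <= 0:
        raise ValueError("zero within-group variance; ANOVA undefined")
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    F = ms_b / ms_w
    p = float(sps.f.sf(F, df_b, df_w))
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        diff = data[i].mean() - data[j].mean()
        se = math.sqrt(ms_w / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(diff) / se
        p_pair = float(sps.studentized_range.sf(q, k, df_w))
        rows.append({"group_1": a, "group_2": b, "mean_diff": diff, "q": q,
                     "p": p_pair, "significant": p_pair < alpha})
    return AnovaResult(
        F=float(F), df=(df_b, df_w), p=p, tukey=pd.DataFrame(rows),
        group_means={g: float(d.mean()) for g, d in zip(labels, data)},
    )
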