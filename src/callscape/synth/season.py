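"""Seasonal detection-count simulator.

Generates per-quarter-hour true and false-positive detection counts over
a season whose daily intensity steps through life-cycle phases (flood
suppression, pre-laying, incubation ramp, a hatching step, post-hatch
plateau, decay, post-breeding), distributed over the clock by a two-peak
(dawn/dusk) or all-day diel profile, with nocturnal counts boosted on
moonlit nights and an independent uniform false-positive stream per
phase.  Each day's true counts sum to a single Poisson draw of that
day's intensity.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..solar import SYNODIC_MONTH_DAYS, moon_age_days

__all__ = [
    "PhaseSpec",
    "SeasonSpec",
    "default_season_spec",
    "simulate_season",
    "expected_daily_intensity",
    "water_measurements",
]

QH_PER_DAY = 96
#: Nights within this many days of full moon count as moonlit (roughly the
#: first-quarter-to-last-quarter span of substantial evening/morning light).
MOONLIT_WINDOW_DAYS = 5.5


@dataclass(frozen=True)
class PhaseSpec:
    """One life-cycle phase: date range, mean daily rate, diel mode, FP rate."""

    name: str
    start_date: dt.date
    end_date: dt.date  # inclusive
    mean_rate: float  # true call events per day
    diel: str = "two_peak"
    fp_rate: float = 0.0  # expected fraction of *total* detections that are false

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError(f"phase {self.name}: end before start")
        if self.mean_rate < 0:
            raise ValueError(f"phase {self.name}: rate must be >= 0")
        if not 0.0 <= self.fp_rate < 1.0:
            raise ValueError(f"phase {self.name}: fp_rate must be in [0, 1)")
        if self.diel not in ("two_peak", "all_day"):
            raise ValueError(f"phase {self.name}: diel must be 'two_peak' or 'all_day'")


@dataclass
class SeasonSpec:
    """Full season description; all randomness flows from ``seed``."""

    phases: list[PhaseSpec]
    lunar_night_multiplier: float = 1.0
    sunrise_hour: float = 6.5
    sunset_hour: float = 17.75
    hatch_step_fraction: float | None = None  # documents how the peak rate was derived
    water_readings: pd.Series | None = None  # cm, indexed by date
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("need at least one phase")
        for prev, cur in zip(self.phases, self.phases[1:]):
            if cur.start_date <= prev.end_date:
                raise ValueError("phase date ranges must be strictly increasing and disjoint")
        if self.lunar_night_multiplier < 1.0:
            raise ValueError("lunar_night_multiplier must be >= 1")

    @property
    def start_date(self) -> dt.date:
        return self.phases[0].start_date

    @property
    def end_date(self) -> dt.date:
        return self.phases[-1].end_date

    def phase_of(self, date: dt.date) -> PhaseSpec | None:
        for p in self.phases:
            if p.start_date <= date <= p.end_date:
                return p
        return None


def default_season_spec(seed: int = 0, lunar_night_multiplier: float = 1.0,
                        hatch_step_fraction: float = 0.64) -> SeasonSpec:
    """Season with the canonical phase structure and rates.

    Phase means step through 19, 110, 467 events/day, jump by the hatch
    step fraction (+64% -> ~766/day), then fall through 489, 220, 43.
    Weekly water readings decline linearly from 42 cm to dry ground over
    the first ten weeks.
    """
    d = dt.date
    ramp_rate = 467.0
    hatch_rate = ramp_rate * (1.0 + hatch_step_fraction)
    phases = [
        PhaseSpec("flood_low", d(2013, 4, 1), d(2013, 4, 25), 19.0, "two_peak", 0.64),
        PhaseSpec("territory", d(2013, 4, 26), d(2013, 5, 20), 110.0, "two_peak", 0.29),
        PhaseSpec("incubation_ramp", d(2013, 5, 21), d(2013, 6, 12), ramp_rate, "two_peak", 0.23),
        PhaseSpec("hatch", d(2013, 6, 13), d(2013, 6, 28), hatch_rate, "all_day", 0.065),
        PhaseSpec("tending", d(2013, 6, 29), d(2013, 7, 8), 489.0, "all_day", 0.065),
        PhaseSpec("decay", d(2013, 7, 9), d(2013, 8, 31), 220.0, "two_peak", 0.06),
        PhaseSpec("post_breeding", d(2013, 9, 1), d(2013, 9, 30), 43.0, "two_peak", 0.31),
    ]
    dates = [d(2013, 4, 1) + dt.timedelta(days=7 * i) for i in range(11)]
    water = pd.Series(np.linspace(42.0, 0.0, len(dates)), index=dates, name="water_cm")
    return SeasonSpec(phases=phases, lunar_night_multiplier=lunar_night_multiplier,
                      hatch_step_fraction=hatch_step_fraction, water_readings=water,
                      seed=seed)


def water_measurements(spec: SeasonSpec) -> pd.Series:
    if spec.water_readings is None:
        raise ValueError("season spec carries no water readings")
    return spec.water_readings


def _diel_weights(spec: SeasonSpec, diel: str) -> np.ndarray:
    """Relative intensity per quarter hour (not normalized)."""
    h = (np.arange(QH_PER_DAY) + 0.5) / 4.0
    dawn, dusk = spec.sunrise_hour, spec.sunset_hour
    if diel == "two_peak":
        w = (np.exp(-0.5 * ((h - dawn) / 0.75) ** 2)
             + np.exp(-0.5 * ((h - dusk) / 0.75) ** 2) + 0.02)
    else:  # all_day: dawn/dusk peaks plus a sustained midday plateau >= 40% of max
        peaks = (np.exp(-0.5 * ((h - dawn) / 1.5) ** 2)
                 + np.exp(-0.5 * ((h - dusk) / 1.5) ** 2))
        plateau = np.where((h > dawn) & (h < dusk), 0.45, 0.0)
        w = np.maximum(peaks, plateau) + 0.02
    return w


def _night_mask(spec: SeasonSpec) -> np.ndarray:
    """Quarter-hour bins outside the day window (sunrise - 1 h .. sunset + 45 min)."""
    h = (np.arange(QH_PER_DAY) + 0.5) / 4.0
    return (h < spec.sunrise_hour - 1.0) | (h > spec.sunset_hour + 0.75)


def is_moonlit(date: dt.date) -> bool:
    """Nights within a few days of full moon count as moonlit."""
    age = moon_age_days(date)
    return abs(age - SYNODIC_MONTH_DAYS / 2.0) <= MOONLIT_WINDOW_DAYS


def _bin_intensities(spec: SeasonSpec, phase: PhaseSpec, date: dt.date) -> np.ndarray:
    w = _diel_weights(spec, phase.diel)
    lam = phase.mean_rate * w / w.sum()
    if spec.lunar_night_multiplier > 1.0 and is_moonlit(date):
        lam = lam.copy()
        lam[_night_mask(spec)] *= spec.lunar_night_multiplier
    return lam


def expected_daily_intensity(spec: SeasonSpec, date: dt.date) -> float:
    """Exact Poisson intensity of the true-count total for a given date."""
    phase = spec.phase_of(date)
    if phase is None:
        raise ValueError(f"{date} falls outside all phases")
    return float(_bin_intensities(spec, phase, date).sum())


def simulate_season(spec: SeasonSpec) -> pd.DataFrame:
    """Draw the season table: one row per (date, quarter hour).

    Columns: ``date`` (datetime.date), ``quarter_hour_index`` (0-95),
    ``true_count``, ``fp_count``, ``night_flag``.  The day's true counts
    are a single Poisson draw of the day's intensity, split across bins
    multinomially in proportion to the diel profile; false positives are
    an independent Poisson stream, uniform over the clock, with expected
    mass ``fp/(1-fp)`` times the phase's true rate.  Deterministic per
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    night = _night_mask(spec)
    records = []
    date = spec.start_date
    one_day = dt.timedelta(days=1)
    while date <= spec.end_date:
        phase = spec.phase_of(date)
        if phase is None:
            date += one_day
            continue
        lam = _bin_intensities(spec, phase, date)
        total_intensity = lam.sum()
        if total_intensity > 0:
            day_total = rng.poisson(total_intensity)
            true_counts = rng.multinomial(day_total, lam / total_intensity)
        else:
            true_counts = np.zeros(QH_PER_DAY, dtype=int)
        fp_intensity = phase.mean_rate * phase.fp_rate / (1.0 - phase.fp_rate)
        fp_counts = rng.poisson(fp_intensity / QH_PER_DAY, size=QH_PER_DAY)
        for b in range(QH_PER_DAY):
            records.append((date, b, int(true_counts[b]), int(fp_counts[b]), bool(night[b])))
        date += one_day
    return pd.DataFrame(records, columns=["date", "quarter_hour_index", "true_count",
                                          "fp_count", "night_flag"])


def write_season_csv(path, table: pd.DataFrame) -> None:
    out = table.copy()
    out["date"] = out["date"].map(lambda d: d.isoformat())
    out["night_flag"] = out["night_flag"].astype(int)
    out.to_csv(path, index=False)
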