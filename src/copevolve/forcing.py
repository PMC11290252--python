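"""Synthetic seasonal environmental forcing for a high-latitude station.

Generates daily series of food (diatoms, non-diatoms, microzooplankton,
detritus; mmol C m^-3) and sea-surface temperature (deg C) emulating the
structure of a Norwegian Sea time-series station: a single dominant spring
bloom whose peak timing varies between years, a sinusoidal SST cycle with a
growing-season mean near 9 deg C, and (once per decade) an anomalously cold
spring with a bloom delayed by about a month.  Deep-water temperature is a
constant (default 4 deg C).

The total food series within a year is a Gaussian pulse over a winter
baseline, partitioned into the four components by fixed fractions.  The
pulse width is derived from the configured bloom-onset day, defined as the
first day total food reaches ``onset_threshold`` (2 mmol C m^-3 by default).

Day indexing is 1-based day-of-year; years are 365 days (no leap years).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("copevolve.forcing")

DAYS_PER_YEAR = 365
#: lookahead appended to assembled sequences so any trajectory spawned in the
#: final year can read two further years of forcing (wrapping to year 1)
LOOKAHEAD_DAYS = 2 * DAYS_PER_YEAR

FOOD_COLUMNS = ("diatom", "nondiatom", "microzoo", "detritus")
FORCING_COLUMNS = ("day",) + FOOD_COLUMNS + ("sst",)


@dataclass(frozen=True)
class AnnualForcingConfig:
    """Parameters of one synthetic forcing year.

    ``bloom_onset_day`` is the day total food first reaches
    ``onset_threshold``; together with ``bloom_peak_day`` it fixes the width
    of the Gaussian bloom pulse.  ``sst_spring_anomaly`` (deg C) is
    subtracted from SST around day 120 to emulate an anomalously cold
    spring.
    """

    bloom_onset_day: int = 120
    bloom_peak_day: int = 150
    peak_food: float = 6.0
    baseline_food: float = 0.3
    food_fractions: tuple[float, float, float, float] = (0.45, 0.30, 0.15, 0.10)
    sst_min: float = 3.5
    sst_max: float = 14.0
    sst_peak_day: int = 225
    sst_spring_anomaly: float = 0.0
    onset_threshold: float = 2.0

    def validate(self) -> None:
        if self.baseline_food < 0:
            raise ValueError(f"baseline_food must be >= 0, got {self.baseline_food}")
        if self.peak_food < self.baseline_food:
            raise ValueError(
                f"peak_food ({self.peak_food}) must be >= baseline_food "
                f"({self.baseline_food})"
            )
        if self.peak_food > self.baseline_food:
            if not self.bloom_onset_day < self.bloom_peak_day:
                raise ValueError(
                    f"bloom_onset_day ({self.bloom_onset_day}) must precede "
                    f"bloom_peak_day ({self.bloom_peak_day})"
                )
            if not self.baseline_food < self.onset_threshold < self.peak_food:
                raise ValueError(
                    f"onset_threshold ({self.onset_threshold}) must lie between "
                    f"baseline_food and peak_food"
                )
        if len(self.food_fractions) != 4 or any(f < 0 for f in self.food_fractions):
            raise ValueError(f"food_fractions must be 4 non-negative values, got {self.food_fractions}")
        if abs(sum(self.food_fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"food_fractions must sum to 1, got sum={sum(self.food_fractions)}"
            )
        if self.sst_max < self.sst_min:
            raise ValueError(f"sst_max ({self.sst_max}) must be >= sst_min ({self.sst_min})")

    @property
    def bloom_sigma(self) -> float:
        """Width (days) of the Gaussian pulse implied by onset and peak days."""
        if self.peak_food == self.baseline_food:
            return 1.0  # irrelevant: zero-amplitude bloom
        rel = (self.peak_food - self.baseline_food) / (
            self.onset_threshold - self.baseline_food
        )
        return (self.bloom_peak_day - self.bloom_onset_day) / math.sqrt(2.0 * math.log(rel))


@dataclass
class ForcingSeries:
    """Day-indexed food and SST series over one or more (possibly repeated) years.

    ``food`` has shape (n_days, 4) in the order diatom, non-diatom,
    microzooplankton, detritus.  Absolute days run 1..n_days; day d of year y
    (1-based) is absolute day (y-1)*365 + d.
    """

    food: np.ndarray
    sst: np.ndarray
    n_years: int = 1
    deep_temperature: float = 4.0

    def __post_init__(self) -> None:
        self.food = np.asarray(self.food, dtype=float)
        self.sst = np.asarray(self.sst, dtype=float)
        if self.food.ndim != 2 or self.food.shape[1] != 4:
            raise ValueError("food must have shape (n_days, 4)")
        if len(self.sst) != len(self.food):
            raise ValueError("food and sst must have equal length")
        if np.any(self.food < 0):
            raise ValueError("food concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.sst)

    @property
    def total_food(self) -> np.ndarray:
        return self.food.sum(axis=1)

    def food_on(self, day: int | np.ndarray) -> np.ndarray:
        return self.food[np.asarray(day) - 1]

    def sst_on(self, day: int | np.ndarray) -> np.ndarray:
        return self.sst[np.asarray(day) - 1]

    def year_slice(self, year: int) -> slice:
        """Index slice for 1-based cycle year ``year``."""
        if not 1 <= year <= self.n_years:
            raise ValueError(f"year must be in 1..{self.n_years}, got {year}")
        start = (year - 1) * DAYS_PER_YEAR
        return slice(start, start + DAYS_PER_YEAR)


def generate_annual_cycle(cfg: AnnualForcingConfig) -> ForcingSeries:
    """Generate one 365-day year of synthetic forcing from ``cfg``.

    Total food is a Gaussian pulse peaking exactly at ``bloom_peak_day``;
    SST is a sinusoid between ``sst_min`` and ``sst_max`` peaking at
    ``sst_peak_day``, minus any configured spring cold anomaly.
    """
    cfg.validate()
    days = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)

    amplitude = cfg.peak_food - cfg.baseline_food
    if amplitude > 0:
        pulse = np.exp(-0.5 * ((days - cfg.bloom_peak_day) / cfg.bloom_sigma) ** 2)
    else:
        pulse = np.zeros_like(days)
    total = cfg.baseline_food + amplitude * pulse
    fractions = np.asarray(cfg.food_fractions, dtype=float)
    food = total[:, None] * fractions[None, :]

    mid = 0.5 * (cfg.sst_min + cfg.sst_max)
    amp = 0.5 * (cfg.sst_max - cfg.sst_min)
    sst = mid + amp * np.cos(2.0 * np.pi * (days - cfg.sst_peak_day) / DAYS_PER_YEAR)
    if cfg.sst_spring_anomaly:
        sst = sst - cfg.sst_spring_anomaly * np.exp(-0.5 * ((days - 120.0) / 40.0) ** 2)

    return ForcingSeries(food=food, sst=sst, n_years=1)


def assemble_sequence(
    years: list[AnnualForcingConfig],
    n_passes: int = 1,
    lookahead_days: int = LOOKAHEAD_DAYS,
) -> ForcingSeries:
    """Concatenate annual cycles end-on-end with cyclic lookahead.

    The sequence of ``len(years) * n_passes`` years is followed by
    ``lookahead_days`` of wraparound (reading the start of the cycle again)
    so that a trajectory spawned late in the final year has two further
    years of forcing available.
    """
    if not years:
        raise ValueError("assemble_sequence requires at least one annual config")
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    annual = [generate_annual_cycle(cfg) for cfg in years]
    base_food = np.concatenate([s.food for s in annual] * n_passes, axis=0)
    base_sst = np.concatenate([s.sst for s in annual] * n_passes)
    if lookahead_days > 0:
        reps = -(-lookahead_days // len(base_sst))
        extra_food = np.tile(base_food, (reps, 1))[:lookahead_days]
        extra_sst = np.tile(base_sst, reps)[:lookahead_days]
        food = np.concatenate([base_food, extra_food], axis=0)
        sst = np.concatenate([base_sst, extra_sst])
    else:
        food, sst = base_food, base_sst
    return ForcingSeries(food=food, sst=sst, n_years=len(years) * n_passes)


def extend_with_wraparound(series: ForcingSeries, lookahead_days: int = LOOKAHEAD_DAYS) -> ForcingSeries:
    """Append cyclic lookahead to a series covering exactly n_years*365 days."""
    base = series.n_years * DAYS_PER_YEAR
    if len(series) < base:
        raise ValueError("series shorter than its declared year count")
    food, sst = series.food[:base], series.sst[:base]
    reps = -(-lookahead_days // base)
    extra_food = np.tile(food, (reps, 1))[:lookahead_days]
    extra_sst = np.tile(sst, reps)[:lookahead_days]
    return ForcingSeries(
        food=np.concatenate([food, extra_food], axis=0),
        sst=np.concatenate([sst, extra_sst]),
        n_years=series.n_years,
        deep_temperature=series.deep_temperature,
    )


def bloom_onset_day(
    series: ForcingSeries, year: int = 1, threshold: float = 2.0
) -> int | None:
    """First day-of-year in cycle year ``year`` on which total food >= threshold.

    Returns None if the threshold is never reached within the year.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    total = series.total_food[series.year_slice(year)]
    hits = np.nonzero(total >= threshold)[0]
    if len(hits) == 0:
        return None
    return int(hits[0]) + 1


def read_forcing_table(path) -> ForcingSeries:
    """Read a forcing CSV (columns day,diatom,nondiatom,microzoo,detritus,sst).

    Records at coarser than daily resolution (e.g. 5-day) are linearly
    interpolated to daily; daily input passes through unchanged.
    """
    df = pd.read_csv(path)
    for col in FORCING_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"forcing table missing required column '{col}'")
    day = df["day"].to_numpy(dtype=float)
    if len(day) == 0:
        raise ValueError("forcing table is empty")
    if np.any(np.diff(day) <= 0):
        raise ValueError("forcing table day column must be strictly increasing")
    for col in FOOD_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        bad = np.nonzero(vals < 0)[0]
        if len(bad):
            raise ValueError(
                f"negative {col} concentration at row {int(bad[0])} "
                f"(day {int(day[bad[0]])})"
            )
    first, last = int(day[0]), int(day[-1])
    if first != 1:
        raise ValueError(f"forcing table must start at day 1, got {first}")
    n_days = max(last, DAYS_PER_YEAR * (last // DAYS_PER_YEAR or 1))
    out_days = np.arange(1, n_days + 1, dtype=float)
    food = np.column_stack(
        [np.interp(out_days, day, df[col].to_numpy(dtype=float)) for col in FOOD_COLUMNS]
    )
    sst = np.interp(out_days, day, df["sst"].to_numpy(dtype=float))
    n_years = max(1, n_days // DAYS_PER_YEAR)
    return ForcingSeries(food=food, sst=sst, n_years=n_years)


def write_forcing_table(series: ForcingSeries, path) -> None:
    """Write the base (non-lookahead) part of a series as a forcing CSV."""
    n = series.n_years * DAYS_PER_YEAR
    n = min(n, len(series))
    df = pd.DataFrame({"day": np.arange(1, n + 1)})
    for j, col in enumerate(FOOD_COLUMNS):
        df[col] = series.food[:n, j]
    df["sst"] = series.sst[:n]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Presets emulating the 10-year station decade

# (bloom_peak_day, bloom_onset_day, peak_food, cold_spring, anomalous) per
# year 1..10.  Peak days span exactly 140 (earliest, year 4) to 170 (latest,
# year 2); years 7 and 9 are early-onset years with large, slow-building
# blooms; years 1, 2, 3, 6, 10 are cold years; year 2 is the anomalous
# cold/late year with bloom onset delayed by ~30 days relative to a typical
# year.  Onset days (first crossing of 2 mmol C m^-3) span roughly two
# months across the decade, a much wider spread than the peak days, which is
# what makes interannual variability consequential for exit timing.
_DECADE_TABLE = (
    (155, 120, 6.0, True, False),
    (170, 144, 8.0, True, True),
    (165, 130, 5.5, True, False),
    (140, 100, 6.5, False, False),
    (150, 110, 6.0, False, False),
    (157, 122, 6.0, True, False),
    (142, 85, 8.0, False, False),
    (148, 108, 6.5, False, False),
    (141, 90, 7.5, False, False),
    (156, 108, 6.0, True, False),
)


def station_mike_year(year: int) -> AnnualForcingConfig:
    """Synthetic forcing config for one year (1..10) of the decade preset."""
    if not 1 <= year <= 10:
        raise ValueError(f"year must be in 1..10, got {year}")
    peak, onset, peak_food, cold, anomalous = _DECADE_TABLE[year - 1]
    return AnnualForcingConfig(
        bloom_onset_day=onset,
        bloom_peak_day=peak,
        peak_food=peak_food,
        sst_min=2.5 if cold else 3.5,
        sst_max=14.0,
        sst_spring_anomaly=2.0 if anomalous else 0.0,
    )


def station_mike_decade() -> list[AnnualForcingConfig]:
    """The full 10-year synthetic decade (one anomalous cold/late year)."""
    return [station_mike_year(y) for y in range(1, 11)]
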