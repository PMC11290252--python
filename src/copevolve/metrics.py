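"""Post-convergence diagnostics: egg fates, fecundity, adult dynamics.

Operates on the per-cell :class:`~copevolve.selection.CellRecord` lists
produced by the analysis pass of the selection engine.  An individual is
attributed to the calendar year of its diapause exit (the year its adult
phase begins), matching how the seasonal analyses are indexed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .forcing import DAYS_PER_YEAR
from .selection import FATE_CATEGORIES, CellRecord

#: decomposition categories in presentation order
DECOMPOSITION_COLUMNS = FATE_CATEGORIES + ("adult_starved",)


def _exit_year(rec: CellRecord, n_years: int) -> int:
    """Calendar (cycle) year of the record's diapause exit."""
    return rec.year % n_years + 1 if n_years > 1 else rec.year


def records_for_exit_year(
    records: list[CellRecord], year: int, n_years: int
) -> list[CellRecord]:
    """Records of individuals whose adults exit diapause in cycle ``year``."""
    return [r for r in records if _exit_year(r, n_years) == year]


def egg_fate_decomposition(records: list[CellRecord]) -> pd.DataFrame:
    """Exhaustive, mutually exclusive egg fates per spawn bin.

    Rows are spawn bins; columns are the development fates (starvation in
    phases 1-3, predation by phase, predation in diapause, survival to
    adult) plus the post-exit adult starvation count.  Per bin, the
    development categories sum to the eggs simulated in that bin.
    """
    bins = sorted({r.spawn_bin for r in records})
    out = pd.DataFrame(0, index=pd.Index(bins, name="spawn_bin"),
                       columns=list(DECOMPOSITION_COLUMNS), dtype=np.int64)
    eggs = pd.Series(0, index=out.index, dtype=np.int64)
    for r in records:
        for cat in FATE_CATEGORIES:
            out.loc[r.spawn_bin, cat] += r.fate.get(cat, 0)
        out.loc[r.spawn_bin, "adult_starved"] += r.adult_starved
        eggs[r.spawn_bin] += r.n_eggs
    bad = eggs[out[list(FATE_CATEGORIES)].sum(axis=1) != eggs]
    if len(bad):
        raise AssertionError(
            f"fate decomposition does not conserve eggs in bins {list(bad.index)}"
        )
    return out


def fecundity_per_female(
    records: list[CellRecord], year: int, n_years: int = 1
) -> float:
    """Average eggs per adult female arriving post-diapause in ``year``.

    Total eggs spawned divided by the number of adults that exited diapause
    that year; NaN when no adults arrived.
    """
    recs = records_for_exit_year(records, year, n_years)
    adults = sum(r.fate.get("adult", 0) for r in recs)
    if adults == 0:
        return float("nan")
    eggs = sum(r.offspring_total for r in recs)
    return eggs / adults


def survivorship(records: list[CellRecord], year: int, n_years: int = 1) -> float:
    """Adults per egg for the cohort whose adults exit in ``year``."""
    recs = records_for_exit_year(records, year, n_years)
    eggs = sum(r.n_eggs for r in recs)
    if eggs == 0:
        return 0.0
    adults = sum(r.fate.get("adult", 0) for r in recs)
    return adults / eggs


def adult_timeseries(
    records: list[CellRecord], year: int, n_years: int = 1
) -> pd.Series:
    """Daily adult counts in ``year``, normalized to total arrivals.

    Adults arrive in 10-day exit pulses and decay daily through predation
    and starvation, producing the characteristic saw-tooth.  The series is
    indexed by day-of-year (1..365) and normalized so total post-diapause
    arrivals equal 1.
    """
    recs = records_for_exit_year(records, year, n_years)
    daily = np.zeros(DAYS_PER_YEAR)
    arrivals = 0
    for r in recs:
        n_adults = r.fate.get("adult", 0)
        arrivals += n_adults
        if len(r.adult_days) == 0:
            continue
        doy = (r.adult_days - 1) % DAYS_PER_YEAR
        in_year = ((r.adult_days - 1) // DAYS_PER_YEAR) == ((r.adult_days[0] - 1) // DAYS_PER_YEAR)
        np.add.at(daily, doy[in_year], r.adult_alive[in_year])
    if arrivals:
        daily = daily / arrivals
    return pd.Series(daily, index=pd.RangeIndex(1, DAYS_PER_YEAR + 1, name="day"))


def starvation_fraction(
    records: list[CellRecord],
    year: int,
    day_window: tuple[int | None, int | None] = (None, None),
    n_years: int = 1,
) -> float:
    """Fraction of post-diapause adults dying of starvation in a day window.

    ``day_window`` bounds (inclusive, day-of-year) filter the starvation
    day; ``None`` leaves a side open.  Denominator is all adults arriving
    post-diapause that year; 0.0 when none arrived.
    """
    recs = records_for_exit_year(records, year, n_years)
    arrivals = sum(r.fate.get("adult", 0) for r in recs)
    if arrivals == 0:
        return 0.0
    lo, hi = day_window
    starved = 0
    for r in recs:
        if r.adult_starved == 0 or r.starved_day is None:
            continue
        doy = (r.starved_day - 1) % DAYS_PER_YEAR + 1
        if (lo is None or doy >= lo) and (hi is None or doy <= hi):
            starved += r.adult_starved
    return starved / arrivals


def decomposition_to_csv(records: list[CellRecord], path) -> None:
    egg_fate_decomposition(records).to_csv(path)


def adult_timeseries_to_csv(
    records: list[CellRecord], years: list[int], n_years: int, path
) -> None:
    df = pd.DataFrame(
        {f"year_{y}": adult_timeseries(records, y, n_years) for y in years}
    )
    df.to_csv(path)
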