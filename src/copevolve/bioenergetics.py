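"""Deterministic daily bioenergetics of one copepod life history.

The life cycle is divided into six phases tied to lipid dynamics:

1. non-feeding egg/nauplius (temperature-dependent timer, 7 d at 10 deg C);
2. feeding and structural growth (NIII-CII);
3. feeding, growth and lipid deposition (to CV), ending when structural
   carbon reaches 6.5 umol C and reserve lipid 7.52 umol C (total 14.0);
4. diapause in deep water, metabolism suppressed 100-fold, fuelled by lipid;
5. gonad development in deep water (14 days, full metabolic rate on lipid);
6. adult female at the surface, income-breeding eggs from assimilated food.

Growth is carbon-only: assimilated Holling type III ingestion (mass-specific,
Q10 = 2) minus basal metabolism (mass-specific on structural carbon, Q10 = 2).
This is a deliberately simplified stand-in for a full stoichiometric (C and N)
individual model: it is exposed entirely through the daily
phase/biomass/egg records of :class:`Trajectory`, so a richer physiological
core can replace it without touching the selection machinery, which consumes
only those records.

A trajectory is keyed by (spawn year, spawn day-of-year, diapause-exit
day-of-year); the exit day always falls in the calendar year after spawning.
Trajectories are precomputed over the full (spawn bin x exit day) grid into a
:class:`TrajectoryStore` so that the multi-generation population model never
re-runs the bioenergetics.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .forcing import DAYS_PER_YEAR, ForcingSeries

logger = logging.getLogger("copevolve.bioenergetics")

#: egg spawn-date bins: 51 bins, 5 days apart, days 50..300 (the growing
#: season; eggs outside this window are non-viable over winter)
SPAWN_BINS = tuple(range(50, 301, 5))
SPAWN_BIN_MIN, SPAWN_BIN_MAX = SPAWN_BINS[0], SPAWN_BINS[-1]


@dataclass(frozen=True)
class BioParams:
    """Physiological parameters of the carbon-only individual model.

    Rates are mass-specific on structural carbon and referenced to
    ``tref_bio``; ``diapause_metab_factor`` suppresses metabolism two orders
    of magnitude during diapause.  ``lipid_at_diapause`` is 80% of the
    original 9.4 umol C reserve criterion (7.52 umol C), giving total
    biomass at diapause entry of 14.0 umol C.
    """

    phase1_days_at_10c: float = 7.0
    dev_q10: float = 2.0
    graz_imax_ref: float = 0.45      # d^-1, max specific ingestion at tref_bio
    graz_half_sat: float = 2.5       # mmol C m^-3
    graz_q10: float = 2.0
    tref_bio: float = 10.0
    assimilation_efficiency: float = 0.7
    basal_metab_ref: float = 0.06    # d^-1 on structural C at tref_bio
    metab_q10: float = 2.0
    diapause_metab_factor: float = 0.01
    gonad_metab_factor: float = 1.0      # phase-5 multiplier on basal rate
    structure_at_diapause: float = 6.5   # umol C
    lipid_at_diapause: float = 7.52      # umol C (= 0.80 * 9.4)
    phase2to3_structure: float = 3.0     # umol C
    phase5_days: int = 14
    egg_carbon: float = 0.023            # umol C per egg
    deep_t: float = 4.0                  # deg C
    max_lifespan_days: int = 730

    def validate(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"BioParams.{f.name} must be positive")
        if self.diapause_metab_factor >= 0.5:
            raise ValueError("diapause_metab_factor must be << 1")


class TrajectoryKey(NamedTuple):
    """(spawn year index, spawn day-of-year bin, exit day-of-year)."""

    spawn_year: int
    spawn_bin: int
    exit_day: int


@dataclass
class Trajectory:
    """Daily record of one deterministic life history.

    ``days`` are absolute days (spawn day first); ``eggs`` are whole eggs
    spawned each day (non-zero only in phase 6); ``deep`` is True exactly
    for phases 4-5.  ``starvation_day`` is the absolute day the individual
    starves (None if the record ends by lifespan/forcing limits while
    alive).  ``viable`` is False when the (spawn, exit) schedule cannot be
    met (e.g. diapause threshold not reached in time): such trajectories
    carry zero fitness.
    """

    key: TrajectoryKey
    days: np.ndarray
    phase: np.ndarray
    structure_c: np.ndarray
    lipid_c: np.ndarray
    eggs: np.ndarray
    deep: np.ndarray
    starvation_day: int | None
    viable: bool

    @property
    def spawn_day(self) -> int:
        return int(self.days[0])

    @property
    def exit_day_abs(self) -> int:
        """Absolute day the adult arrives at the surface."""
        return self.key.spawn_year * DAYS_PER_YEAR + self.key.exit_day

    @property
    def total_eggs(self) -> int:
        return int(self.eggs.sum())

    def __len__(self) -> int:
        return len(self.days)


def _q10(rate_ref: float, t: float, q10: float, tref: float) -> float:
    return rate_ref * q10 ** ((t - tref) / 10.0)


def phase1_duration(t: float, p: BioParams | None = None) -> int:
    """Days spent as non-feeding egg/nauplius at temperature ``t``.

    Temperature-dependent (Q10) development taking ``phase1_days_at_10c``
    at 10 deg C, rounded up to whole days for the daily time step.
    """
    p = p or BioParams()
    if not math.isfinite(t):
        raise ValueError("temperature must be finite")
    return int(math.ceil(p.phase1_days_at_10c * p.dev_q10 ** ((10.0 - t) / 10.0)))


def grazing_rate(food, t: float, p: BioParams | None = None) -> float:
    """Specific ingestion rate (d^-1 on structural C) for feeding phases.

    Multiple-resource sigmoidal (Holling type III) response on total food
    with a temperature-dependent maximum (Q10 = 2).  Feeding occurs only in
    phases 2, 3 and 6; callers handle the non-feeding phases.
    """
    p = p or BioParams()
    food = np.asarray(food, dtype=float)
    if np.any(food < 0):
        raise ValueError("food concentrations must be non-negative")
    s = float(food.sum())
    imax = _q10(p.graz_imax_ref, t, p.graz_q10, p.tref_bio)
    return imax * s * s / (p.graz_half_sat**2 + s * s)


@dataclass
class IndividualState:
    """Mutable daily state used by :func:`step_individual`."""

    phase: int = 1
    structure_c: float = 0.023
    lipid_c: float = 0.0
    phase1_days_left: int = 0
    egg_pool: float = 0.0        # carbon carried between phase-6 days
    eggs_today: int = 0
    starved: bool = False


def step_individual(
    state: IndividualState,
    food,
    sst: float,
    p: BioParams,
    *,
    enter_phase5: bool = False,
    enter_phase6: bool = False,
) -> IndividualState:
    """Advance one individual by one day in place.

    Phase transitions 4->5 and 5->6 are schedule-driven (14 days before and
    at the diapause-exit day) and signalled by the caller; transitions
    1->2, 2->3 and 3->4 are state-driven (timer and biomass thresholds,
    checked at day end).  Starvation occurs when reserves are exhausted and
    the day's carbon balance is negative.
    """
    state.eggs_today = 0
    if enter_phase5:
        state.phase = 5
    if enter_phase6:
        state.phase = 6

    ph = state.phase
    if ph == 1:
        state.phase1_days_left -= 1
        if state.phase1_days_left <= 0:
            state.phase = 2
        return state

    if ph in (4, 5):
        t = p.deep_t
        factor = p.diapause_metab_factor if ph == 4 else p.gonad_metab_factor
        loss = factor * _q10(p.basal_metab_ref, t, p.metab_q10, p.tref_bio) * state.structure_c
        state.lipid_c -= loss
        if state.lipid_c <= 0.0:
            state.lipid_c = 0.0
            state.starved = True
        return state

    # surface feeding phases 2, 3, 6
    intake = grazing_rate(food, sst, p) * state.structure_c
    metab = _q10(p.basal_metab_ref, sst, p.metab_q10, p.tref_bio) * state.structure_c
    net = p.assimilation_efficiency * intake - metab

    if net >= 0.0:
        if ph == 2:
            state.structure_c += net
            if state.structure_c >= p.phase2to3_structure:
                state.phase = 3
        elif ph == 3:
            if state.structure_c < p.structure_at_diapause:
                to_struct = min(0.5 * net, p.structure_at_diapause - state.structure_c)
            else:
                to_struct = 0.0
            state.structure_c += to_struct
            state.lipid_c += net - to_struct
            if (
                state.structure_c >= p.structure_at_diapause
                and state.lipid_c >= p.lipid_at_diapause
            ):
                state.phase = 4
        else:  # phase 6
            state.egg_pool += net
            state.eggs_today = int(state.egg_pool // p.egg_carbon)
            state.egg_pool -= state.eggs_today * p.egg_carbon
    else:
        # negative balance: draw down lipid reserves; starve when exhausted
        state.lipid_c += net
        if state.lipid_c <= 0.0:
            state.lipid_c = 0.0
            state.starved = True
    return state


def simulate_trajectory(
    key: TrajectoryKey, forcing: ForcingSeries, p: BioParams | None = None
) -> Trajectory:
    """Simulate one deterministic life history for ``key`` under ``forcing``.

    The individual exits diapause (enters the 14-day gonad phase) 14 days
    before the exit day and spawns eggs from the exit day while food lasts.
    Pure function: identical inputs give bit-identical trajectories.
    """
    p = p or BioParams()
    spawn_abs = (key.spawn_year - 1) * DAYS_PER_YEAR + key.spawn_bin
    exit_abs = key.spawn_year * DAYS_PER_YEAR + key.exit_day
    phase5_start = exit_abs - p.phase5_days
    end_abs = min(spawn_abs + p.max_lifespan_days - 1, len(forcing))
    if end_abs < spawn_abs:
        raise ValueError(f"forcing does not cover spawn day {spawn_abs}")

    state = IndividualState(
        phase=1,
        structure_c=p.egg_carbon,
        lipid_c=0.0,
        phase1_days_left=phase1_duration(float(forcing.sst_on(spawn_abs)), p),
    )

    rec_day, rec_phase, rec_struct, rec_lipid, rec_eggs = [], [], [], [], []
    starvation_day: int | None = None
    viable = True

    day = spawn_abs
    while day <= end_abs:
        enter5 = enter6 = False
        if day == phase5_start:
            if state.phase != 4:
                viable = False  # missed the diapause schedule: zero fitness
                starvation_day = day
                break
            enter5 = True
        elif day == exit_abs:
            enter6 = True

        # schedule-driven transitions apply at day start, state-driven ones
        # (timer, biomass thresholds) at day end: the recorded phase is the
        # phase the day was lived in
        phase_lived = 5 if enter5 else (6 if enter6 else state.phase)
        step_individual(
            state, forcing.food_on(day), float(forcing.sst_on(day)), p,
            enter_phase5=enter5, enter_phase6=enter6,
        )
        rec_day.append(day)
        rec_phase.append(phase_lived)
        rec_struct.append(state.structure_c)
        rec_lipid.append(state.lipid_c)
        rec_eggs.append(state.eggs_today)
        if state.starved:
            starvation_day = day
            break
        day += 1

    phase_arr = np.asarray(rec_phase, dtype=np.int8)
    return Trajectory(
        key=key,
        days=np.asarray(rec_day, dtype=np.int32),
        phase=phase_arr,
        structure_c=np.asarray(rec_struct, dtype=float),
        lipid_c=np.asarray(rec_lipid, dtype=float),
        eggs=np.asarray(rec_eggs, dtype=np.int32),
        deep=(phase_arr == 4) | (phase_arr == 5),
        starvation_day=starvation_day,
        viable=viable,
    )


class TrajectoryStore:
    """Exact-key lookup of precomputed trajectories.

    One trajectory per (spawn year, spawn bin, exit day) over the full grid;
    the selection engine performs exact-key retrieval only.
    """

    def __init__(
        self,
        trajectories: dict[TrajectoryKey, Trajectory],
        spawn_bins: tuple[int, ...],
        exit_grid: tuple[int, ...],
        n_years: int,
    ):
        self._traj = trajectories
        self.spawn_bins = tuple(spawn_bins)
        self.exit_grid = tuple(exit_grid)
        self.n_years = n_years

    def __len__(self) -> int:
        return len(self._traj)

    def __contains__(self, key: TrajectoryKey) -> bool:
        return key in self._traj

    def keys(self):
        return self._traj.keys()

    def lookup(self, key: TrajectoryKey) -> Trajectory:
        try:
            return self._traj[key]
        except KeyError:
            raise KeyError(
                f"no stored trajectory for key (year={key[0]}, "
                f"spawn_bin={key[1]}, exit_day={key[2]})"
            ) from None

    # -- persistence (single indexed CSV, bit-exact reload) ----------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self._traj):
            tr = self._traj[key]
            rows.append(
                pd.DataFrame(
                    {
                        "year": key.spawn_year,
                        "spawn_bin": key.spawn_bin,
                        "exit_day": key.exit_day,
                        "day": tr.days,
                        "phase": tr.phase,
                        "structure_c": tr.structure_c,
                        "lipid_c": tr.lipid_c,
                        "eggs": tr.eggs,
                        "deep": tr.deep.astype(int),
                        "starved": np.int8(tr.starvation_day is not None),
                        "viable": np.int8(tr.viable),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def save_csv(self, path) -> None:
        # 17 significant digits round-trip any float64 bit-exactly
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def load_csv(cls, path) -> "TrajectoryStore":
        df = pd.read_csv(path, float_precision="round_trip")
        trajectories: dict[TrajectoryKey, Trajectory] = {}
        for (year, sbin, exd), grp in df.groupby(["year", "spawn_bin", "exit_day"], sort=True):
            key = TrajectoryKey(int(year), int(sbin), int(exd))
            phase = grp["phase"].to_numpy(dtype=np.int8)
            starved = bool(grp["starved"].iloc[0])
            days = grp["day"].to_numpy(dtype=np.int32)
            trajectories[key] = Trajectory(
                key=key,
                days=days,
                phase=phase,
                structure_c=grp["structure_c"].to_numpy(dtype=float),
                lipid_c=grp["lipid_c"].to_numpy(dtype=float),
                eggs=grp["eggs"].to_numpy(dtype=np.int32),
                deep=grp["deep"].to_numpy(dtype=bool),
                starvation_day=int(days[-1]) if starved else None,
                viable=bool(grp["viable"].iloc[0]),
            )
        spawn_bins = tuple(sorted(df["spawn_bin"].unique()))
        exit_grid = tuple(sorted(df["exit_day"].unique()))
        n_years = int(df["year"].max())
        return cls(trajectories, spawn_bins, exit_grid, n_years)


def build_lookup(
    forcing: ForcingSeries,
    spawn_bins: Iterable[int] = SPAWN_BINS,
    exit_grid: Iterable[int] = tuple(range(50, 201, 10)),
    p: BioParams | None = None,
    years: Iterable[int] | None = None,
) -> TrajectoryStore:
    """Precompute trajectories for every (year, spawn bin, exit day).

    ``years`` defaults to every cycle year of ``forcing``; the forcing must
    include a two-year lookahead past the final year.
    """
    p = p or BioParams()
    spawn_bins = tuple(spawn_bins)
    exit_grid = tuple(exit_grid)
    if not spawn_bins or not exit_grid:
        raise ValueError("spawn_bins and exit_grid must be non-empty")
    years = tuple(years) if years is not None else tuple(range(1, forcing.n_years + 1))
    if len(forcing) < years[-1] * DAYS_PER_YEAR:
        raise ValueError("forcing too short for requested years")
    trajectories: dict[TrajectoryKey, Trajectory] = {}
    for year in years:
        for sbin in spawn_bins:
            for exd in exit_grid:
                key = TrajectoryKey(year, sbin, exd)
                trajectories[key] = simulate_trajectory(key, forcing, p)
        logger.debug("built trajectories for year %d (%d keys)", year, len(trajectories))
    return TrajectoryStore(trajectories, spawn_bins, exit_grid, max(years))


def lookup(store: TrajectoryStore, key: TrajectoryKey) -> Trajectory:
    """Exact-key retrieval from a :class:`TrajectoryStore`."""
    return store.lookup(key)


def params_hash(forcing: ForcingSeries, p: BioParams) -> str:
    """Stable content hash used for idempotent store rebuilds."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(forcing.food).tobytes())
    h.update(np.ascontiguousarray(forcing.sst).tobytes())
    h.update(repr(p).encode())
    return h.hexdigest()[:16]
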