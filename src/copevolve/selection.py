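"""Multi-generation natural-selection loop over the trait grid.

Each generation: every egg realizes a diapause-exit day from its inherited
trait, follows the precomputed trajectory for its (spawn year, spawn bin,
exit day), faces daily stochastic predation and deterministic starvation,
and — if it survives to adulthood — contributes its trajectory's daily egg
schedule (binned to the nearest 5-day spawn bin, with the parent's trait)
until its own death.  A fixed number of eggs, n_pop, is passed forward by
frequency-preserving (largest-remainder) resampling.  Selection proceeds
until a single trait remains (strict fixation), after which extra years are
simulated with full per-cell records for the diagnostic analyses.

All stochastic sampling is performed cohort-wise with multinomial draws
whose laws are exactly those of independent per-individual daily Bernoulli
draws; RNG is consumed in a fixed canonical cell order so results are
independent of any iteration-order concerns and fully reproducible from the
run seed.

Because every viable trajectory exits diapause in the calendar year after
spawning, each generation advances the forcing-year index by exactly one
(wrapping around the year cycle); the cohort therefore carries a single
spawn-year index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bioenergetics import (
    DAYS_PER_YEAR,
    SPAWN_BINS,
    TrajectoryKey,
    TrajectoryStore,
)
from .forcing import ForcingSeries
from .mortality import MortalityParams, daily_mortality
from .traits import EXIT_GRID, SDPV_GRID, TraitPair, exit_day_distribution, trait_grid

logger = logging.getLogger("copevolve.selection")

FATE_CATEGORIES = (
    "predated_phase1",
    "predated_phase2",
    "predated_phase3",
    "starved_development",
    "predated_diapause",
    "adult",
)


class ExtinctionError(RuntimeError):
    """The whole sub-population died before producing offspring."""


@dataclass
class RunConfig:
    """Configuration of one evolutionary run.

    The full-scale defaults give 100 eggs per (trait x spawn bin) cell at
    initialization; :meth:`desk` is the scaled-down preset (2 eggs per cell)
    used for testing and exploratory runs.
    """

    n_pop_init: int = 408_000
    n_pop_reduced: int = 100_000
    reduce_after_generation: int = 20
    max_generations: int = 400
    convergence_extra_years: int = 10
    seed: int = 0
    forced_sdpv: int | None = None
    start_year: int = 1

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "RunConfig":
        kw.setdefault("n_pop_init", 8_160)
        kw.setdefault("n_pop_reduced", 4_080)
        return cls(seed=seed, **kw)


@dataclass
class EggCohort:
    """Egg counts per (trait, spawn bin) for one spawn year.

    ``counts`` has shape (n_traits, n_bins); ``year`` is the 1-based index
    of the forcing-cycle year the eggs are spawned in.
    """

    traits: list[TraitPair]
    bins: tuple[int, ...]
    counts: np.ndarray
    year: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.traits), len(self.bins)):
            raise ValueError("counts shape must be (n_traits, n_bins)")
        if np.any(self.counts < 0):
            raise ValueError("egg counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def trait_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def frequencies(self) -> np.ndarray:
        tot = self.total
        if tot == 0:
            raise ValueError("empty cohort has no frequencies")
        return self.counts / tot


@dataclass
class GenerationSummary:
    generation: int
    year: int
    n_eggs: int
    fate_totals: dict[str, int]
    n_adults: int
    n_offspring: int
    eggs_per_female: float
    survivorship: float
    trait_counts: dict[TraitPair, int]
    converged: bool = False
    dominant_trait: TraitPair | None = None


@dataclass
class CellRecord:
    """Aggregated per-(spawn bin, exit day) outcome of one analysis year.

    ``adult_days`` are the absolute days of the adult (phase 6) part of the
    trajectory; ``adult_alive[i]`` is the number of adults still alive at
    the end of ``adult_days[i]``.  ``eggs_per_day`` is the per-capita daily
    egg schedule of the trajectory.
    """

    year: int
    spawn_bin: int
    exit_day: int
    n_eggs: int
    fate: dict[str, int]
    adult_days: np.ndarray
    adult_alive: np.ndarray
    eggs_per_day: np.ndarray
    offspring_total: int
    adult_pred_deaths: int
    adult_starved: int
    starved_day: int | None


@dataclass
class RunResult:
    converged: bool
    dominant_trait: TraitPair | None
    n_generations: int
    summaries: list[GenerationSummary]
    analysis_records: list[CellRecord]
    config: RunConfig


class _CellStats:
    """Precomputed stochastic-fate quantities for one stored trajectory."""

    __slots__ = (
        "fate_probs", "dd_probs", "n_p6", "terminal_starved", "starved_day",
        "days6", "eggs6", "seg_starts", "seg_child", "exp_offspring",
    )

    def __init__(self, traj, forcing: ForcingSeries, mp: MortalityParams, bins: tuple[int, ...]):
        p = daily_mortality(traj, forcing, mp)
        one_minus = 1.0 - p
        surv_before = np.empty(len(p))
        surv_before[0] = 1.0
        if len(p) > 1:
            np.cumprod(one_minus[:-1], out=surv_before[1:])
        death_at = surv_before * p

        phase = traj.phase
        fate = np.zeros(6)
        fate[0] = death_at[phase == 1].sum()
        fate[1] = death_at[phase == 2].sum()
        fate[2] = death_at[phase == 3].sum()
        fate[4] = death_at[(phase == 4) | (phase == 5)].sum()
        idx6 = np.nonzero(phase == 6)[0]
        other = fate[[0, 1, 2, 4]].sum()
        if len(idx6):
            # reaching phase 6 counts as the 'adult' fate; deaths within
            # phase 6 are resolved separately by the death-day distribution
            adult_prob = max(1.0 - other, 0.0)
            fate[5] = adult_prob
        else:
            # survived all predation but the trajectory ended pre-adult
            # (starvation during development or a missed diapause schedule)
            adult_prob = 0.0
            fate[3] = max(1.0 - other, 0.0)
        self.fate_probs = fate / fate.sum()

        self.terminal_starved = traj.starvation_day is not None
        self.starved_day = traj.starvation_day
        if len(idx6):
            p6 = p[idx6]
            cond_alive = np.cumprod(1.0 - p6)
            cond_before = np.empty(len(p6))
            cond_before[0] = 1.0
            cond_before[1:] = cond_alive[:-1]
            dd = cond_before * p6
            survive_end = max(1.0 - dd.sum(), 0.0)
            dd_probs = np.append(dd, survive_end)
            self.dd_probs = dd_probs / dd_probs.sum()
            self.n_p6 = len(p6)
            self.days6 = traj.days[idx6]
            eggs6 = traj.eggs[idx6].astype(float)
            doy = (self.days6 - 1) % DAYS_PER_YEAR + 1
            child_bin = 5 * ((doy + 2) // 5)
            bin_index = {b: i for i, b in enumerate(bins)}
            child_idx = np.array([bin_index.get(int(b), -1) for b in child_bin])
            eggs6[child_idx < 0] = 0.0  # out-of-window eggs are non-viable
            self.eggs6 = eggs6
            changes = np.nonzero(np.diff(child_idx))[0] + 1
            self.seg_starts = np.concatenate([[0], changes])
            self.seg_child = child_idx[self.seg_starts]
            exp_off = np.zeros(len(bins))
            weights = adult_prob * cond_alive * eggs6
            np.add.at(exp_off, np.maximum(child_idx, 0), weights)
            exp_off[0] -= weights[child_idx < 0].sum()
            self.exp_offspring = exp_off
        else:
            self.dd_probs = np.array([1.0])
            self.n_p6 = 0
            self.days6 = np.empty(0, dtype=np.int32)
            self.eggs6 = np.empty(0)
            self.seg_starts = np.empty(0, dtype=np.int64)
            self.seg_child = np.empty(0, dtype=np.int64)
            self.exp_offspring = np.zeros(len(bins))


class SelectionEngine:
    """Binds a trajectory store, forcing and mortality into a runnable engine.

    Precomputes, per stored trajectory, the exact per-phase fate
    probabilities, the conditional adult death-day distribution and the
    expected-offspring kernel used by both the stochastic generation loop
    and the deterministic fitness oracle.
    """

    def __init__(
        self,
        store: TrajectoryStore,
        forcing: ForcingSeries,
        mp: MortalityParams | None = None,
    ):
        self.store = store
        self.forcing = forcing
        self.mp = mp or MortalityParams()
        self.mp.validate()
        self.bins = store.spawn_bins
        self.exit_grid = store.exit_grid
        self.years = tuple(sorted({k.spawn_year for k in store.keys()}))
        self.n_years = len(self.years)

        nb, ne = len(self.bins), len(self.exit_grid)
        self.fate_p: dict[int, np.ndarray] = {}
        self.cells: dict[int, dict[tuple[int, int], _CellStats]] = {}
        self.exp_off: dict[int, np.ndarray] = {}
        for year in self.years:
            fp = np.zeros((nb, ne, 6))
            cells: dict[tuple[int, int], _CellStats] = {}
            eo = np.zeros((nb, ne, nb))
            for bi, sbin in enumerate(self.bins):
                for ei, exd in enumerate(self.exit_grid):
                    traj = store.lookup(TrajectoryKey(year, sbin, exd))
                    cs = _CellStats(traj, forcing, self.mp, self.bins)
                    fp[bi, ei] = cs.fate_probs
                    cells[(bi, ei)] = cs
                    eo[bi, ei] = cs.exp_offspring
            self.fate_p[year] = fp
            self.cells[year] = cells
            self.exp_off[year] = eo
        logger.debug("engine ready: %d years, %d bins, %d exits", self.n_years, nb, ne)

    # ------------------------------------------------------------------

    def exit_pvals(self, traits: Sequence[TraitPair]) -> np.ndarray:
        return np.stack([exit_day_distribution(t, self.exit_grid) for t in traits])

    def next_year(self, year: int) -> int:
        return year % self.n_years + 1 if self.n_years > 1 else year

    def run_generation(
        self,
        cohort: EggCohort,
        rng: np.random.Generator,
        record_cells: bool = False,
    ) -> tuple[EggCohort, GenerationSummary, list[CellRecord]]:
        """Simulate one generation: fates of every egg, offspring collection.

        Returns the raw offspring cohort (un-resampled, spawn year advanced
        by one), a summary, and per-cell records when ``record_cells``.
        """
        year = self.years[(cohort.year - 1) % self.n_years]
        active = np.nonzero(cohort.trait_totals() > 0)[0]
        counts = cohort.counts[active]
        traits_a = [cohort.traits[i] for i in active]
        na, nb = counts.shape
        ne = len(self.exit_grid)

        pvals = self.exit_pvals(traits_a)                      # (na, ne)
        X = rng.multinomial(counts, pvals[:, None, :])         # (na, nb, ne)
        F = rng.multinomial(X, self.fate_p[year][None, :, :, :])  # (na, nb, ne, 6)
        adults = F[..., 5]

        offspring = np.zeros((na, nb), dtype=np.int64)
        cells = self.cells[year]
        records: list[CellRecord] = []
        adult_pred_total = 0
        adult_starved_total = 0
        for bi in range(nb):
            for ei in range(ne):
                a = adults[:, bi, ei]
                a_tot = int(a.sum())
                cs = cells[(bi, ei)]
                if a_tot == 0 or cs.n_p6 == 0:
                    if record_cells and X[:, bi, ei].sum() > 0:
                        records.append(self._empty_record(year, bi, ei, X, F, cs))
                    continue
                dd = rng.multinomial(a, cs.dd_probs)           # (na, K+1)
                deaths = dd[:, : cs.n_p6]
                alive_after = a[:, None] - np.cumsum(deaths, axis=1)
                seg = np.add.reduceat(
                    alive_after * cs.eggs6[None, :], cs.seg_starts, axis=1
                )
                valid = cs.seg_child >= 0
                if valid.any():
                    # np.add.at: segments may revisit a child bin (day-of-year
                    # wrap under constant forcing), so duplicates must accumulate
                    np.add.at(
                        offspring,
                        (slice(None), cs.seg_child[valid]),
                        np.rint(seg[:, valid]).astype(np.int64),
                    )
                end_alive = dd[:, cs.n_p6].sum()
                if cs.terminal_starved:
                    adult_starved_total += int(end_alive)
                adult_pred_total += a_tot - int(end_alive)
                if record_cells:
                    records.append(
                        CellRecord(
                            year=year,
                            spawn_bin=self.bins[bi],
                            exit_day=self.exit_grid[ei],
                            n_eggs=int(X[:, bi, ei].sum()),
                            fate={
                                c: int(F[:, bi, ei, j].sum())
                                for j, c in enumerate(FATE_CATEGORIES)
                            },
                            adult_days=cs.days6.copy(),
                            adult_alive=alive_after.sum(axis=0),
                            eggs_per_day=cs.eggs6.copy(),
                            offspring_total=int(np.rint(seg[:, valid].sum())) if valid.any() else 0,
                            adult_pred_deaths=a_tot - int(end_alive),
                            adult_starved=int(end_alive) if cs.terminal_starved else 0,
                            starved_day=cs.starved_day,
                        )
                    )

        n_adults = int(adults.sum())
        n_off = int(offspring.sum())
        fate_totals = {
            c: int(F[..., j].sum()) for j, c in enumerate(FATE_CATEGORIES)
        }
        out_counts = np.zeros_like(cohort.counts)
        out_counts[active] = offspring
        out = EggCohort(
            traits=cohort.traits,
            bins=cohort.bins,
            counts=out_counts,
            year=self.next_year(cohort.year),
        )
        summary = GenerationSummary(
            generation=-1,
            year=year,
            n_eggs=cohort.total,
            fate_totals=fate_totals,
            n_adults=n_adults,
            n_offspring=n_off,
            eggs_per_female=(n_off / n_adults) if n_adults else float("nan"),
            survivorship=(n_adults / cohort.total) if cohort.total else 0.0,
            trait_counts={t: int(c) for t, c in zip(cohort.traits, cohort.trait_totals()) if c},
        )
        return out, summary, records

    def _empty_record(self, year, bi, ei, X, F, cs) -> CellRecord:
        return CellRecord(
            year=year,
            spawn_bin=self.bins[bi],
            exit_day=self.exit_grid[ei],
            n_eggs=int(X[:, bi, ei].sum()),
            fate={c: int(F[:, bi, ei, j].sum()) for j, c in enumerate(FATE_CATEGORIES)},
            adult_days=np.empty(0, dtype=np.int32),
            adult_alive=np.empty(0, dtype=np.int64),
            eggs_per_day=np.empty(0),
            offspring_total=0,
            adult_pred_deaths=0,
            adult_starved=0,
            starved_day=cs.starved_day,
        )

    # ------------------------------------------------------------------

    def expected_fitness(
        self, trait: TraitPair, start_year: int = 1
    ) -> float:
        """Deterministic long-run eggs-per-egg growth factor of a trait.

        Builds the expected offspring projection matrix over spawn bins for
        each year of the cycle (survival probability x egg schedule,
        weighted by the trait's realized-exit mass) and returns the
        geometric-mean per-generation growth rate — the dominant eigenvalue
        of the cycle product, to the power 1/n_years.  No sampling.
        """
        pv = exit_day_distribution(trait, self.exit_grid)
        nb = len(self.bins)
        prod = np.eye(nb)
        for step in range(self.n_years):
            year = self.years[(start_year - 1 + step) % self.n_years]
            m = np.tensordot(self.exp_off[year], pv, axes=([1], [0]))  # (nb_parent, nb_child)
            prod = m.T @ prod
        lam = np.max(np.abs(np.linalg.eigvals(prod)))
        return float(lam ** (1.0 / self.n_years))

    def oracle_argmax(self, traits: Sequence[TraitPair] | None = None) -> TraitPair:
        """Trait maximizing the deterministic expected-fitness oracle."""
        traits = list(traits) if traits is not None else trait_grid(self.exit_grid, SDPV_GRID)
        fits = [self.expected_fitness(t) for t in traits]
        return traits[int(np.argmax(fits))]


def expected_fitness_oracle(
    trait: TraitPair, engine: SelectionEngine, start_year: int = 1
) -> float:
    """Functional alias for :meth:`SelectionEngine.expected_fitness`."""
    return engine.expected_fitness(trait, start_year)


# ----------------------------------------------------------------------
# population bookkeeping


def init_population(
    cfg: RunConfig,
    traits: Sequence[TraitPair] | None = None,
    bins: Sequence[int] = SPAWN_BINS,
) -> EggCohort:
    """Uniform initial allocation: n_pop_init spread evenly over all
    (trait x spawn bin) cells; rejects non-divisible population sizes."""
    if traits is None:
        sdpvs = SDPV_GRID if cfg.forced_sdpv is None else (cfg.forced_sdpv,)
        traits = trait_grid(EXIT_GRID, sdpvs)
    traits = list(traits)
    n_cells = len(traits) * len(bins)
    if cfg.n_pop_init % n_cells:
        raise ValueError(
            f"n_pop_init ({cfg.n_pop_init}) must be divisible by the number "
            f"of trait x spawn-bin cells ({n_cells})"
        )
    per_cell = cfg.n_pop_init // n_cells
    counts = np.full((len(traits), len(bins)), per_cell, dtype=np.int64)
    return EggCohort(traits=traits, bins=tuple(bins), counts=counts, year=cfg.start_year)


def resample_offspring(
    cohort: EggCohort, n_pop: int, rng: np.random.Generator
) -> EggCohort:
    """Resample to exactly ``n_pop`` eggs, preserving cell frequencies.

    Largest-remainder proportional allocation: each cell receives the floor
    of its proportional share; leftover eggs go to the cells with the
    largest remainders, ties broken by the RNG.  Each cell is within 1 of
    its exact proportional share.
    """
    total = cohort.total
    if total == 0:
        raise ExtinctionError("no offspring to resample: population extinct")
    flat = cohort.counts.ravel()
    share = flat * (n_pop / total)
    base = np.floor(share).astype(np.int64)
    leftover = n_pop - int(base.sum())
    if leftover:
        rem = share - base
        order = np.lexsort((rng.random(len(flat)), -rem))
        base[order[:leftover]] += 1
    return EggCohort(
        traits=cohort.traits,
        bins=cohort.bins,
        counts=base.reshape(cohort.counts.shape),
        year=cohort.year,
    )


def check_convergence(cohort: EggCohort) -> tuple[bool, TraitPair]:
    """Converged iff exactly one trait has a nonzero count."""
    totals = cohort.trait_totals()
    if cohort.total == 0:
        raise ValueError("empty cohort: convergence undefined")
    nonzero = np.nonzero(totals)[0]
    dominant = cohort.traits[int(np.argmax(totals))]
    return len(nonzero) == 1, dominant


def run_to_convergence(
    cfg: RunConfig,
    engine: SelectionEngine,
    traits: Sequence[TraitPair] | None = None,
    bins: Sequence[int] | None = None,
) -> RunResult:
    """Run generations until strict trait fixation (or max_generations).

    Applies the n_pop schedule (reduction after ``reduce_after_generation``),
    then simulates ``convergence_extra_years`` further generations with full
    per-cell records for the metrics module.  Non-convergence is reported on
    the result (and logged), not raised; extinction raises
    :class:`ExtinctionError`.
    """
    rng = np.random.default_rng(cfg.seed)
    bins = tuple(bins) if bins is not None else engine.bins
    if traits is None:
        sdpvs = SDPV_GRID if cfg.forced_sdpv is None else (cfg.forced_sdpv,)
        traits = trait_grid(engine.exit_grid, sdpvs)
    cohort = init_population(cfg, traits=traits, bins=bins)
    summaries: list[GenerationSummary] = []
    converged, dominant = False, None

    for g in range(1, cfg.max_generations + 1):
        offspring, summary, _ = engine.run_generation(cohort, rng)
        summary.generation = g
        if offspring.total == 0:
            raise ExtinctionError(f"population extinct at generation {g}")
        n_pop = cfg.n_pop_init if g <= cfg.reduce_after_generation else cfg.n_pop_reduced
        cohort = resample_offspring(offspring, n_pop, rng)
        converged, dominant = check_convergence(cohort)
        summary.converged = converged
        summary.dominant_trait = dominant
        summaries.append(summary)
        if converged:
            logger.info("trait fixation at generation %d: %s", g, dominant)
            break
    if not converged:
        logger.warning(
            "no trait fixation within %d generations (dominant: %s)",
            cfg.max_generations,
            dominant,
        )

    records: list[CellRecord] = []
    for extra in range(cfg.convergence_extra_years):
        offspring, summary, recs = engine.run_generation(cohort, rng, record_cells=True)
        records.extend(recs)
        if offspring.total == 0:
            break
        cohort = resample_offspring(offspring, cfg.n_pop_reduced, rng)

    return RunResult(
        converged=converged,
        dominant_trait=dominant,
        n_generations=len(summaries),
        summaries=summaries,
        analysis_records=records,
        config=cfg,
    )
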