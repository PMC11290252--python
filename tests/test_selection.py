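import numpy as np
import pytest
from hypothesis import given, strategies as st

import copevolve as cv
from copevolve.bioenergetics import TrajectoryKey, TrajectoryStore, simulate_trajectory
from copevolve.mortality import MortalityParams
from copevolve.selection import (
    EggCohort,
    ExtinctionError,
    RunConfig,
    SelectionEngine,
    check_convergence,
    init_population,
    resample_offspring,
    run_to_convergence,
)
from copevolve.traits import TraitPair, trait_grid


def make_uniform_store(bins, exits, egg_scale=None, forcing=None):
    """Store in which the SAME life history backs every (bin, exit) key.

    ``egg_scale`` optionally maps exit day -> fecundity multiplier, which
    creates a controlled fitness difference between exit days while leaving
    everything else identical.
    """
    if forcing is None:
        forcing = cv.ForcingSeries(
            food=np.full((3 * 365, 4), 8.0), sst=np.full(3 * 365, 9.0), n_years=1
        )
    base = simulate_trajectory(TrajectoryKey(1, bins[0], exits[0]), forcing, cv.BioParams())
    assert base.total_eggs > 0
    trajectories = {}
    for b in bins:
        for e in exits:
            traj = base
            if egg_scale is not None:
                traj = cv.Trajectory(
                    key=base.key,
                    days=base.days,
                    phase=base.phase,
                    structure_c=base.structure_c,
                    lipid_c=base.lipid_c,
                    eggs=base.eggs * egg_scale.get(e, 1),
                    deep=base.deep,
                    starvation_day=base.starvation_day,
                    viable=base.viable,
                )
            trajectories[TrajectoryKey(1, b, e)] = traj
    return TrajectoryStore(trajectories, tuple(bins), tuple(exits), 1), forcing


class TestInitPopulation:
    def test_full_scale_gives_100_eggs_per_cell(self):
        cohort = init_population(RunConfig())
        assert cohort.counts.shape == (80, 51)
        assert np.all(cohort.counts == 100)

    def test_unit_allocation(self):
        cohort = init_population(RunConfig(n_pop_init=4080))
        assert np.all(cohort.counts == 1)

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            init_population(RunConfig(n_pop_init=4081))

    def test_forced_sdpv_restricts_grid_to_16_traits(self):
        cohort = init_population(RunConfig(n_pop_init=816, forced_sdpv=0))
        assert len(cohort.traits) == 16
        assert all(t.sdpv == 0 for t in cohort.traits)


class TestResampleOffspring:
    def _cohort(self, counts):
        counts = np.atleast_2d(np.asarray(counts, dtype=np.int64))
        traits = [TraitPair(50 + 10 * i, 0) for i in range(counts.shape[0])]
        bins = tuple(50 + 5 * j for j in range(counts.shape[1]))
        return EggCohort(traits=traits, bins=bins, counts=counts)

    def test_single_cell_gets_everything(self):
        out = resample_offspring(self._cohort([[7]]), 1000, np.random.default_rng(0))
        assert out.counts[0, 0] == 1000

    def test_even_split_is_exact(self):
        out = resample_offspring(self._cohort([[30, 30]]), 1000, np.random.default_rng(0))
        assert out.counts.tolist() == [[500, 500]]

    def test_largest_remainder_thirds(self):
        out = resample_offspring(self._cohort([[10, 10, 10]]), 100, np.random.default_rng(0))
        assert sorted(out.counts.ravel().tolist()) == [33, 33, 34]

    def test_extinct_cohort_raises(self):
        with pytest.raises(ExtinctionError):
            resample_offspring(self._cohort([[0, 0]]), 100, np.random.default_rng(0))

    @given(
        st.lists(st.integers(0, 10_000), min_size=2, max_size=40).filter(lambda c: sum(c) > 0),
        st.integers(1, 5_000),
    )
    def test_frequencies_preserved_within_one_egg_per_cell(self, counts, n_pop):
        cohort = self._cohort([counts])
        out = resample_offspring(cohort, n_pop, np.random.default_rng(3))
        assert out.total == n_pop
        exact = np.asarray(counts) * n_pop / sum(counts)
        assert np.all(np.abs(out.counts.ravel() - exact) < 1.0)


class TestCheckConvergence:
    def _cohort(self, counts):
        traits = [TraitPair(110, 20), TraitPair(120, 0)]
        return EggCohort(traits=traits, bins=(50,), counts=np.asarray(counts))

    def test_single_surviving_trait_converges(self):
        conv, dom = check_convergence(self._cohort([[10], [0]]))
        assert conv and dom == TraitPair(110, 20)

    def test_two_traits_not_converged(self):
        conv, _ = check_convergence(self._cohort([[10], [1]]))
        assert not conv

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            check_convergence(self._cohort([[0], [0]]))


class TestRunGeneration:
    def test_every_egg_has_exactly_one_fate(self, year7_engine):
        cohort = init_population(
            RunConfig(n_pop_init=8160), bins=year7_engine.bins
        )
        rng = np.random.default_rng(5)
        _, summary, _ = year7_engine.run_generation(cohort, rng)
        assert sum(summary.fate_totals.values()) == cohort.total == 8160

    def test_zero_mortality_single_trait_is_deterministic(self):
        bins, exits = (100, 150), (80,)
        store, forcing = make_uniform_store(bins, exits)
        mp = MortalityParams(m1_ref=0.0, m2=0.0, m3_ref=0.0)
        engine = SelectionEngine(store, forcing, mp)
        traits = [TraitPair(80, 0)]
        cohort = EggCohort(
            traits=traits, bins=bins, counts=np.array([[10, 20]]), year=1
        )
        offspring, summary, _ = engine.run_generation(cohort, np.random.default_rng(0))
        traj = store.lookup(TrajectoryKey(1, 100, 80))
        # no predation and a trajectory that reaches adulthood: every egg is
        # an adult and contributes its full egg schedule, of which exactly
        # the eggs binned into the store's spawn bins become offspring
        doy = (traj.days[traj.phase == 6] - 1) % 365 + 1
        eggs6 = traj.eggs[traj.phase == 6]
        viable_eggs = eggs6[np.isin(5 * ((doy + 2) // 5), bins)].sum()
        assert summary.n_adults == 30
        assert summary.n_offspring == 30 * viable_eggs
        assert offspring.total == summary.n_offspring

    def test_reproducible_for_fixed_seed(self, year7_engine):
        cohort = init_population(RunConfig(n_pop_init=8160), bins=year7_engine.bins)
        a, _, _ = year7_engine.run_generation(cohort, np.random.default_rng(11))
        b, _, _ = year7_engine.run_generation(cohort, np.random.default_rng(11))
        assert np.array_equal(a.counts, b.counts)

    def test_twofold_fecundity_advantage_doubles_frequency_ratio(self):
        """Selection oracle: with a 2x egg-schedule advantage and no
        mortality, the trait frequency ratio doubles every generation."""
        bins, exits = (100, 150), (80, 110)
        store, forcing = make_uniform_store(bins, exits, egg_scale={110: 2})
        mp = MortalityParams(m1_ref=0.0, m2=0.0, m3_ref=0.0)
        engine = SelectionEngine(store, forcing, mp)
        traits = [TraitPair(80, 0), TraitPair(110, 0)]
        cohort = EggCohort(
            traits=traits, bins=bins, counts=np.full((2, 2), 50_000), year=1
        )
        rng = np.random.default_rng(2)
        for _ in range(3):
            offspring, _, _ = engine.run_generation(cohort, rng)
            cohort = resample_offspring(offspring, 200_000, rng)
        totals = cohort.trait_totals()
        ratio = totals[1] / totals[0]
        assert ratio == pytest.approx(8.0, rel=0.02)

    def test_neutral_traits_drift_without_systematic_bias(self):
        """Identical trajectories and mortality for all traits: the trait
        frequency is a martingale, so the replicate-mean final frequency
        stays at its initial value."""
        bins, exits = (100, 150), (80, 110)
        store, forcing = make_uniform_store(bins, exits)
        engine = SelectionEngine(store, forcing, MortalityParams())
        traits = [TraitPair(80, 0), TraitPair(110, 0)]
        finals = []
        for rep in range(40):
            rng = np.random.default_rng(100 + rep)
            cohort = EggCohort(
                traits=traits, bins=bins, counts=np.full((2, 2), 100), year=1
            )
            for _ in range(10):
                offspring, _, _ = engine.run_generation(cohort, rng)
                if offspring.total == 0:
                    break
                cohort = resample_offspring(offspring, 400, rng)
            finals.append(cohort.trait_totals()[0] / max(cohort.total, 1))
        finals = np.asarray(finals)
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - 0.5) < 3 * max(se, 0.01)


class TestRunToConvergence:
    def test_single_trait_converges_immediately(self, year7_engine):
        cfg = RunConfig(n_pop_init=1020, convergence_extra_years=0, seed=0)
        res = run_to_convergence(cfg, year7_engine, traits=[TraitPair(90, 0)])
        assert res.converged and res.n_generations == 1
        assert res.dominant_trait == TraitPair(90, 0)

    def test_forced_sdpv_zero_restricts_and_converges_sdpv0(self, year7_engine):
        cfg = RunConfig.desk(seed=3, forced_sdpv=0, convergence_extra_years=0)
        res = run_to_convergence(cfg, year7_engine)
        assert res.dominant_trait.sdpv == 0

    def test_analysis_pass_produces_records(self, year7_engine):
        cfg = RunConfig.desk(seed=1, convergence_extra_years=1)
        res = run_to_convergence(cfg, year7_engine)
        assert res.converged
        assert len(res.analysis_records) > 0
        rec_eggs = sum(r.n_eggs for r in res.analysis_records)
        assert rec_eggs == cfg.n_pop_reduced


class TestExpectedFitnessOracle:
    def test_zero_mortality_oracle_equals_trajectory_fecundity_growth(self):
        bins, exits = (100, 150), (80,)
        store, forcing = make_uniform_store(bins, exits)
        mp = MortalityParams(m1_ref=0.0, m2=0.0, m3_ref=0.0)
        engine = SelectionEngine(store, forcing, mp)
        traj = store.lookup(TrajectoryKey(1, 100, 80))
        # every egg becomes an adult producing the full schedule; offspring
        # land in viable bins, so the per-generation growth factor is the
        # number of viable eggs per egg
        child_ok = 0
        doy = (traj.days[traj.phase == 6] - 1) % 365 + 1
        eggs6 = traj.eggs[traj.phase == 6]
        child_bins = 5 * ((doy + 2) // 5)
        valid = np.isin(child_bins, bins)
        child_ok = eggs6[valid].sum()
        lam = engine.expected_fitness(TraitPair(80, 0))
        assert lam == pytest.approx(child_ok, rel=1e-9)

    def test_oracle_ranks_match_converged_traits(self, year7_engine):
        best = year7_engine.oracle_argmax()
        fits = {t: year7_engine.expected_fitness(t) for t in trait_grid()}
        assert fits[best] == max(fits.values())
        # repeat-year predictable forcing: variance is of no benefit
        assert best.sdpv == 0
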