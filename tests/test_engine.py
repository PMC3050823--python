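"""Population stepping, bookkeeping, determinism and summaries."""

import numpy as np
import pytest

from epiclone import (
    AlphaSchedule,
    EcologyState,
    ModelParams,
    RunRecord,
    seed_clone,
    seed_mass,
    simulate,
    step_population,
    summarize_replicates,
)

NO_ECOLOGY = EcologyState(enabled=False)
QUIET = AlphaSchedule.constant(0.0, 0.0)


def _run(pop, schedule, params, rng, stop, ecology=NO_ECOLOGY, **kw):
    return simulate(pop, schedule, ecology, params, stop, rng, **kw)


class TestSeeding:
    def test_clone_is_one_naive_progenitor(self, params):
        pop = seed_clone(P0=0.0, t0=0.0, params=params)
        assert len(pop) == 1
        assert pop.g[0] == 0.0 and pop.F[0] == 0.0
        assert np.isnan(pop.k_fixed[0])  # programmed mode
        assert pop.effective_k(params)[0] == 0.0

    def test_mass_clamps_negative_k_draws(self, params, rng):
        pop = seed_mass(10_000, ("normal", 0.3, 1.0), 0.01, params, rng)
        k = pop.effective_k(params)
        assert (k >= 0).all()
        assert (k == 0).any()

    def test_mass_k_median_matches_distribution(self, params, rng):
        pop = seed_mass(10_000, ("normal", 2.0, 0.5), 0.01, params, rng)
        se = 0.5 * 1.2533 / np.sqrt(10_000)  # SE of a normal median
        assert abs(np.median(pop.effective_k(params)) - 2.0) < 3 * se

    def test_constant_k_assignment(self, params, rng):
        pop = seed_mass(50, 1.9, 0.01, params, rng)
        assert (pop.effective_k(params) == 1.9).all()

    def test_programmed_senescent_seed_starts_transformed(self, params, rng):
        pop = seed_mass(
            5, 0.0, 0.005, params, rng, mode="programmed", senescent=True
        )
        assert (pop.effective_k(params) == 0.0).all()
        assert pop.senescent.all()


class TestStepping:
    def test_empty_population_is_fixed_point(self, params, rng):
        pop = seed_clone(0.0, 0.0, params)
        pop = step_population(pop, AlphaSchedule.constant(-5.0, 0.0), NO_ECOLOGY,
                              params, rng)
        assert len(pop) == 0  # the progenitor died
        before_t = pop.t
        pop = step_population(pop, QUIET, NO_ECOLOGY, params, rng)
        assert len(pop) == 0
        assert pop.t == before_t + params.dt

    def test_neutral_fixed_point_is_dormant(self, params, rng):
        # P=0, k=0, alpha=0: all derivatives vanish
        pop = seed_mass(1, 0.0, 0.0, params, rng, g0=0.0)
        for _ in range(50):
            pop = step_population(pop, QUIET, NO_ECOLOGY, params, rng)
        assert len(pop) == 1
        assert pop.P[0] == 0.0 and pop.F[0] == 0.0

    def test_division_doubles_count_and_resets_accumulator(self, params, rng):
        pop = seed_mass(1, 0.0, 1.0, params, rng, g0=0.0)
        pop = step_population(pop, QUIET, NO_ECOLOGY, params, rng)
        assert len(pop) == 2
        assert (pop.F == 0.0).all()
        assert pop.cumulative_divisions == 1
        assert (pop.ids == [1, 2]).all()  # parent id retired

    def test_bookkeeping_reconciles_every_step(self, params):
        rng = np.random.default_rng(7)
        pop = seed_mass(100, ("normal", 1.0, 1.0), ("normal", 0.1, 0.2), params, rng)
        record = _run(
            pop, AlphaSchedule.constant(0.0, 0.1), params, rng,
            {"t_max": 120, "size_cap": 5_000}, check_bookkeeping=True,
        )
        assert record.n_dead_cum[-1] == pop.cumulative_deaths

    def test_mutations_fire_on_generation_crossings(self, params, rng):
        params = params.with_overrides(mutations_per_generation=3)
        pop = seed_mass(1, 0.0, 0.6, params, rng, g0=0.0, mode="programmed")
        pop.mutation_sum[:] = 0.0
        pop = step_population(pop, QUIET, NO_ECOLOGY, params, rng)
        assert pop.n_mutations[0] == 0  # g went 0 -> 0.6, no integer crossed
        pop = step_population(pop, QUIET, NO_ECOLOGY, params, rng)
        assert (pop.n_mutations >= 3).all()  # crossed g=1

    def test_fixed_mode_ignores_mutations(self, params, rng):
        params = params.with_overrides(mutations_per_generation=5)
        pop = seed_mass(1, 1.0, 0.6, params, rng, g0=0.0)
        for _ in range(5):
            pop = step_population(pop, QUIET, NO_ECOLOGY, params, rng)
        assert (pop.n_mutations == 0).all()


class TestDeterminism:
    def _record(self, seed, params):
        rng = np.random.default_rng(seed)
        pop = seed_mass(30, ("normal", 1.5, 0.5), ("normal", 0.05, 0.05), params, rng)
        return _run(
            pop, AlphaSchedule.constant(0.01, 0.05), params, rng,
            {"t_max": 90, "size_cap": 2_000},
            ecology=EcologyState(enabled=True, sigma_floor=0.001),
        )

    def test_identical_seed_gives_identical_trajectories(self, params):
        a = self._record(99, params)
        b = self._record(99, params)
        for name in ("day", "n_live", "n_dead_cum", "median_k", "mean_P"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
        assert a.stop_reason == b.stop_reason

    def test_different_seed_diverges(self, params):
        a = self._record(99, params)
        b = self._record(100, params)
        assert not np.array_equal(a.n_live, b.n_live)


class TestEcologyFeedback:
    def test_disabled_ecology_is_invariant_to_its_parameters(self, params):
        outs = []
        for q, beta, n_basic in [(1.0, 1.0, 18_800.0), (9.0, 5.0, 10.0)]:
            rng = np.random.default_rng(5)
            eco = EcologyState(enabled=False, q=q, beta=beta, n_basic=n_basic)
            pop = seed_mass(20, 0.5, 0.05, params, rng)
            rec = _run(pop, AlphaSchedule.constant(0.0, 0.02), params, rng,
                       {"t_max": 60}, ecology=eco)
            outs.append(rec.n_live)
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_negative_feedback_suppresses_growing_mass(self, params):
        # k=0 mass under positive drive: ecology strictly reduces 6-month size
        sched = AlphaSchedule.constant(0.02, 0.002)
        sizes = {}
        for enabled in (False, True):
            finals = []
            for s in range(15):
                rng = np.random.default_rng(1000 + s)
                pop = seed_mass(1, 0.0, 0.01, params, rng)
                rec = _run(pop, sched, params, rng,
                           {"t_max": 180, "size_cap": 200_000},
                           ecology=EcologyState(enabled=enabled))
                finals.append(rec.n_live[-1])
            sizes[enabled] = np.median(finals)
        assert sizes[True] < sizes[False]


class TestSummaries:
    def _toy_record(self, values, stop="t_max"):
        n = len(values)
        arr = np.asarray(values, dtype=float)
        return RunRecord(
            day=np.arange(n, dtype=float),
            n_live=np.asarray(values, dtype=np.int64),
            n_dead_cum=np.zeros(n, dtype=np.int64),
            median_k=arr * 0.1,
            mean_P=arr * 0.0,
            stop_reason=stop,
        )

    def test_single_replicate_collapses_to_itself(self):
        rec = self._toy_record([1, 2, 4, 8])
        s = summarize_replicates([rec])
        q = s.series["n_live"]
        for col in range(5):
            np.testing.assert_array_equal(q[:, col], [1, 2, 4, 8])

    def test_quantiles_are_ordered_pointwise(self, rng):
        records = [
            self._toy_record(rng.integers(0, 100, size=30)) for _ in range(11)
        ]
        q = summarize_replicates(records).series["n_live"]
        assert (np.diff(q, axis=1) >= 0).all()

    def test_constant_records_summarize_to_constant(self):
        records = [self._toy_record([7, 7, 7])] * 101
        q = summarize_replicates(records).series["n_live"]
        assert (q == 7).all()

    def test_extinct_runs_pad_with_zero(self):
        records = [
            self._toy_record([5, 2, 0], stop="extinct"),
            self._toy_record([5, 5, 5, 5, 5]),
        ]
        q = summarize_replicates(records).series["n_live"]
        np.testing.assert_array_equal(q[:, 0], [5, 2, 0, 0, 0])  # min curve
        np.testing.assert_array_equal(q[:, 4], [5, 5, 5, 5, 5])  # max curve

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_replicates([])

    def test_csv_roundtrip_shape(self, tmp_path):
        rec = self._toy_record([1, 2, 3])
        path = tmp_path / "run.csv"
        rec.to_csv(path)
        text = path.read_text()
        assert text.splitlines()[0] == "day,n_live,n_dead_cum,median_k,mean_P"
        assert len(text.splitlines()) == 4
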