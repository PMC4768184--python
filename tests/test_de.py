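import numpy as np
import pytest

from sigmaevolve.de import DEConfig, quality_index, mutate, run_de, select

from _reference import reference_run_de


class TestQualityIndex:
    def test_identity_is_zero(self):
        v = np.array([0.1, 0.9, 0.4])
        assert quality_index(v, v) == 0.0

    def test_mean_absolute_distance(self):
        assert quality_index([0.3, 0.6], [0.2, 0.8]) == pytest.approx(0.15)

    def test_monitored_subset(self):
        assert quality_index([0.3, 0.6], [0.2, 0.8], np.array([0])) == pytest.approx(0.1)

    def test_empty_monitored_set_rejected(self):
        with pytest.raises(ValueError):
            quality_index([0.1], [0.2], np.array([], dtype=int))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            quality_index([0.1, 0.2], [0.1])


class TestMutate:
    def test_mutation_function_value(self):
        # x_r1 + F (x_r2 - x_r3) = 0.5 + 0.1 * (0.7 - 0.2) = 0.55 on every
        # coordinate; with CR=1 the whole trial is mutant
        pop = np.array([[0.0], [0.5], [0.7], [0.2]])
        rng = np.random.default_rng(0)
        found = set()
        for _ in range(200):
            trial = mutate(pop, 0, f=0.1, cr=1.0, rng=rng)
            found.add(round(float(trial[0]), 10))
        # all donor orderings of {0.5, 0.7, 0.2} with F=0.1
        expected = {0.55, 0.45, 0.73, 0.67, 0.18, 0.22}
        assert found <= expected
        assert 0.55 in found

    def test_f_zero_copies_a_donor(self):
        pop = np.random.default_rng(1).random((6, 8))
        rng = np.random.default_rng(2)
        trial = mutate(pop, 0, f=0.0, cr=1.0, rng=rng)
        assert any(np.allclose(trial, pop[r]) for r in range(1, 6))

    def test_clipping_to_unit_interval(self):
        pop = np.array([[0.5], [0.99], [1.0], [0.0]])
        rng = np.random.default_rng(3)
        for _ in range(50):
            trial = mutate(pop, 3, f=2.0, cr=1.0, rng=rng)
            assert 0.0 <= trial[0] <= 1.0

    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            mutate(np.zeros((3, 2)), 0, 0.1, 0.4, np.random.default_rng(0))


class TestSelect:
    def test_closer_trial_wins(self):
        target = np.zeros(2)
        assert np.allclose(select(np.full(2, 0.2), np.full(2, 0.1), target), 0.1)

    def test_closer_parent_survives(self):
        target = np.zeros(2)
        assert np.allclose(select(np.full(2, 0.1), np.full(2, 0.2), target), 0.1)

    def test_tie_goes_to_trial(self):
        target = np.zeros(2)
        parent = np.array([0.1, 0.1])
        trial = np.array([0.2, 0.0])  # same mean distance, different vector
        assert np.allclose(select(parent, trial, target), trial)


class TestRunDE:
    def test_small_problem_converges(self):
        target = np.random.default_rng(5).random(5)
        cfg = DEConfig(pop_size=30, max_generations=5000, rng_seed=6)
        traj, best = run_de(target, None, cfg)
        assert traj.success
        assert traj.best_qi_per_generation[-1] < 0.001
        assert quality_index(best, target) < 0.001

    def test_forced_stagnation_stops_at_window(self):
        target = np.random.default_rng(5).random(30)
        cfg = DEConfig(
            stagnation_window=50,
            stagnation_min_decrease=np.inf,
            max_generations=10_000,
            rng_seed=1,
        )
        traj, _ = run_de(target, None, cfg)
        assert traj.stop_reason == "stagnation"
        assert traj.generations_run == 50

    def test_seed_determinism(self):
        target = np.random.default_rng(2).random(20)
        cfg = DEConfig(max_generations=200, rng_seed=9)
        t1, b1 = run_de(target, None, cfg)
        t2, b2 = run_de(target, None, cfg)
        assert t1.best_qi_per_generation == t2.best_qi_per_generation
        assert np.array_equal(b1, b2)

    def test_zero_generation_budget(self):
        target = np.random.default_rng(2).random(10)
        cfg = DEConfig(max_generations=0, rng_seed=0)
        traj, _ = run_de(target, None, cfg)
        assert traj.generations_run == 0
        assert not traj.success

    def test_best_qi_non_increasing_and_bounded(self):
        target = np.random.default_rng(11).random(40)
        cfg = DEConfig(max_generations=400, rng_seed=12)
        traj, best = run_de(target, None, cfg)
        qi = np.asarray(traj.best_qi_per_generation)
        assert np.all(np.diff(qi) <= 1e-15)
        assert np.all((best >= 0) & (best <= 1))

    def test_monitored_series_recorded(self):
        target = np.random.default_rng(3).random(30)
        cfg = DEConfig(max_generations=100, rng_seed=4)
        traj, _ = run_de(target, None, cfg, monitored_indices=np.arange(5))
        assert len(traj.monitored_qi_per_generation) == len(traj.best_qi_per_generation)

    def test_cr_zero_changes_exactly_one_coordinate(self):
        # with CR=0 only the forced coordinate is mutated, so parent and
        # trial differ in at most one position; verify via the reference
        # loop implementation's trial construction
        rng = np.random.default_rng(7)
        pop = rng.random((5, 12))
        trial = mutate(pop, 2, f=0.5, cr=0.0, rng=rng)
        assert int((trial != pop[2]).sum()) <= 1


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_vectorized_matches_naive_reference(self, seed):
        """Engine and loop-based reference share the RNG stream and must
        produce bit-identical trajectories."""
        target = np.random.default_rng(100 + seed).random(8)
        cfg = DEConfig(
            pop_size=6,
            max_generations=50,
            qi_success_threshold=1e-12,
            stagnation_window=10_000,
            rng_seed=seed,
        )
        traj_v, _ = run_de(target, None, cfg, rng=np.random.default_rng(seed))
        traj_r = reference_run_de(target, None, cfg, np.random.default_rng(seed))
        assert traj_v.generations_run == traj_r.generations_run == 50
        assert traj_v.evaluations == traj_r.evaluations
        np.testing.assert_allclose(
            traj_v.best_qi_per_generation, traj_r.best_qi_per_generation, rtol=0, atol=1e-12
        )

    def test_equivalence_with_f_zero(self):
        target = np.random.default_rng(55).random(8)
        cfg = DEConfig(
            pop_size=6, cr=0.4, f=0.0, max_generations=30,
            qi_success_threshold=1e-12, stagnation_window=10_000, rng_seed=3,
        )
        traj_v, _ = run_de(target, None, cfg, rng=np.random.default_rng(3))
        traj_r = reference_run_de(target, None, cfg, np.random.default_rng(3))
        np.testing.assert_allclose(
            traj_v.best_qi_per_generation, traj_r.best_qi_per_generation, atol=1e-12
        )


@pytest.mark.parametrize(
    "kwargs",
    [
        {"pop_size": 3},
        {"cr": 1.5},
        {"f": -0.1},
        {"f": 2.5},
        {"qi_success_threshold": 0.0},
        {"stagnation_window": 0},
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        DEConfig(**kwargs)
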