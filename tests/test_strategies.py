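import numpy as np
import pytest

from sigmaevolve.de import DEConfig, quality_index
from sigmaevolve.genome import make_partition, random_partition
from sigmaevolve.strategies import (
    compare_strategies,
    delta_n,
    evolve_genome_strategy,
    evolve_sigma_strategy,
)
from sigmaevolve.targets import random_target


def quick_config(**kw):
    defaults = dict(pop_size=60, max_generations=4000, rng_seed=0)
    defaults.update(kw)
    return DEConfig(**defaults)


class TestDeltaN:
    def test_first_crossing_index(self):
        assert delta_n([0.5, 0.2, 0.009, 0.001], 0.01) == 2

    def test_series_starting_below_threshold(self):
        assert delta_n([0.005, 0.001], 0.01) == 0

    def test_never_crossing_is_missing(self):
        assert delta_n([0.5, 0.4], 0.01) is None

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            delta_n([], 0.01)


class TestGenomeStrategy:
    def test_converges_on_small_genome(self):
        target = random_target(50, 3)
        rr = evolve_genome_strategy(target, quick_config())
        assert rr.success
        assert rr.delta_n is not None
        assert rr.generations_total == rr.generations_max_block

    def test_zero_budget_fails_cleanly(self):
        target = random_target(20, 3)
        rr = evolve_genome_strategy(target, quick_config(max_generations=0))
        assert not rr.success
        assert rr.generations_total == 0

    def test_deterministic_given_seed(self):
        target = random_target(30, 4)
        a = evolve_genome_strategy(target, quick_config(rng_seed=5))
        b = evolve_genome_strategy(target, quick_config(rng_seed=5))
        assert a.trajectory.best_qi_per_generation == b.trajectory.best_qi_per_generation


class TestSigmaStrategy:
    def test_single_block_equals_genome_strategy(self):
        """A degenerate one-block partition must reproduce the genome
        strategy exactly (same RNG substream)."""
        target = random_target(40, 6)
        partition = make_partition(40, [40])
        cfg = quick_config(rng_seed=8, max_generations=500)
        g = evolve_genome_strategy(target, cfg)
        s = evolve_sigma_strategy(target, partition, cfg)
        assert g.trajectory.best_qi_per_generation == s.trajectory.best_qi_per_generation
        assert g.success == s.success
        np.testing.assert_array_equal(g.final_candidate, s.final_candidate)

    def test_final_qi_decomposes_over_blocks(self):
        target = random_target(60, 2)
        partition = make_partition(60, [10, 25, 5, 20])
        rr = evolve_sigma_strategy(target, partition, quick_config(max_generations=300))
        per_block = [
            t.best_qi_per_generation[-1] for t in rr.block_trajectories
        ]
        weighted = np.average(per_block, weights=partition.sizes)
        assert rr.final_qi == pytest.approx(weighted, rel=1e-9)
        # and it matches the QI of the assembled candidate
        assert quality_index(rr.final_candidate, target) == pytest.approx(
            rr.final_qi, rel=1e-9
        )

    def test_all_blocks_below_threshold_implies_genome_success(self):
        target = random_target(30, 9)
        partition = make_partition(30, [10, 10, 10])
        rr = evolve_sigma_strategy(target, partition, quick_config())
        assert rr.success
        assert rr.final_qi < 0.001  # convexity of the weighted mean

    def test_singleton_blocks_converge_almost_immediately(self):
        target = random_target(12, 2)
        partition = make_partition(12, [1] * 12)
        rr = evolve_sigma_strategy(target, partition, quick_config())
        assert rr.success
        assert rr.generations_max_block <= 60

    def test_accounting_sum_and_max(self):
        target = random_target(45, 1)
        partition = make_partition(45, [15, 15, 15])
        rr = evolve_sigma_strategy(target, partition, quick_config(max_generations=200))
        gens = [t.generations_run for t in rr.block_trajectories]
        assert rr.generations_total == sum(gens)
        assert rr.generations_max_block == max(gens)
        assert rr.evaluations_total == sum(t.evaluations for t in rr.block_trajectories)

    def test_partition_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evolve_sigma_strategy(
                random_target(10, 0), make_partition(12, [12]), quick_config()
            )

    def test_monitored_delta_n_uses_regulon_series(self):
        target = random_target(60, 7)
        partition = make_partition(60, [20, 40])
        monitored = np.arange(10)
        rr = evolve_sigma_strategy(
            target, partition, quick_config(), monitored_indices=monitored
        )
        assert rr.monitored_trajectory is not None
        assert rr.delta_n == delta_n(rr.monitored_trajectory, 0.01)


class TestCompareStrategies:
    def test_shapes_and_summaries(self):
        cfg = quick_config(max_generations=800, rng_seed=21)
        comp = compare_strategies(3, 40, 4, cfg)
        assert comp.n_replicates == 3
        recs = comp.to_records()
        assert len(recs) == 6
        assert set(comp.summaries) == {"genome", "sigma"}

    def test_fisher_p_is_one_when_both_always_succeed(self):
        cfg = quick_config(max_generations=5000, rng_seed=2)
        comp = compare_strategies(4, 25, 3, cfg)
        assert comp.success_table[0][0] == 4
        assert comp.success_table[1][0] == 4
        assert comp.fisher_p == pytest.approx(1.0)

    def test_single_replicate_has_no_fisher_p(self):
        cfg = quick_config(max_generations=100)
        comp = compare_strategies(1, 30, 3, cfg)
        assert comp.fisher_p is None

    def test_modular_advantage_in_evaluations_small_scale(self):
        """Even at modest genome size the per-block runs need far fewer
        coordinate evaluations than the joint run."""
        cfg = quick_config(pop_size=100, max_generations=6000, rng_seed=31)
        comp = compare_strategies(3, 150, 5, cfg)
        evals_g = [r.evaluations_total for r in comp.genome_runs]
        evals_s = [r.evaluations_total for r in comp.sigma_runs]
        assert sum(s < g for s, g in zip(evals_s, evals_g)) >= 2
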