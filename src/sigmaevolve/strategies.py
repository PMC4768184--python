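"""Whole-genome vs sigma-factor-block evolution strategies.

The same target transcription factor can be evolved either *genome-based*
(one DE run over all G coordinates at once) or *sigma-factor-based*
(independent DE runs inside each block of a sigma partition, whose winners
are concatenated).  Both cost accountings the field cares about are kept:
the *sum* of per-block generations/evaluations (the serial-CPU reading,
used for headline comparisons) and the *maximum* over blocks (the parallel
reading).

Per-generation trajectories of the sigma strategy are combined into a
parallel view: after a block stops, its best QI is carried forward
unchanged, and the genome-wide QI at generation g is the size-weighted mean
of the per-block values — mean absolute distance decomposes exactly over a
partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .de import DEConfig, Trajectory, run_de
from .genome import SigmaPartition, random_partition
from .stats import fisher_exact
from .targets import random_target

__all__ = [
    "RunResult",
    "ComparisonResult",
    "evolve_genome_strategy",
    "evolve_sigma_strategy",
    "compare_strategies",
    "delta_n",
]


def delta_n(monitored_qi_series: Sequence[float], threshold: float) -> Optional[int]:
    """First generation index at which the QI series drops below threshold.

    Returns ``None`` (missing) if the series never crosses.
    """
    series = np.asarray(monitored_qi_series, dtype=float)
    if series.size == 0:
        raise ValueError("QI series must be non-empty")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    below = np.flatnonzero(series < threshold)
    return int(below[0]) if below.size else None


@dataclass
class RunResult:
    """Outcome of one strategy run on one target."""

    strategy: str  # "genome" or "sigma"
    trajectory: Trajectory
    generations_total: int
    generations_max_block: int
    evaluations_total: int
    cpu_seconds: float
    success: bool
    monitored_trajectory: Optional[list[float]] = None
    delta_n: Optional[int] = None
    final_qi: float = float("nan")
    final_candidate: Optional[np.ndarray] = None
    partial_success_fraction: Optional[float] = None
    block_trajectories: Optional[list[Trajectory]] = None

    def __post_init__(self) -> None:
        if self.strategy == "genome" and self.generations_total != self.generations_max_block:
            raise ValueError("genome strategy: total and max-block generations must agree")
        if self.generations_total > 0 and self.evaluations_total < self.generations_total:
            raise ValueError("at least one evaluation per generation expected")


def _strategy_rng(rng_seed: int, block_index: int) -> np.random.Generator:
    # one substream per block; block 0's substream is also the genome
    # strategy's, so a single-block partition reproduces it exactly
    return np.random.default_rng([abs(int(rng_seed)), block_index])


def evolve_genome_strategy(
    target: np.ndarray,
    config: DEConfig,
    monitored_indices: Optional[np.ndarray] = None,
    delta_n_threshold: float = 0.01,
) -> RunResult:
    """Single DE run across all genome coordinates at once."""
    target = np.asarray(target, dtype=float)
    traj, best = run_de(
        target,
        None,
        config,
        rng=_strategy_rng(config.rng_seed, 0),
        monitored_indices=monitored_indices,
    )
    mon = traj.monitored_qi_per_generation
    dn_series = mon if mon else traj.best_qi_per_generation
    return RunResult(
        strategy="genome",
        trajectory=traj,
        generations_total=traj.generations_run,
        generations_max_block=traj.generations_run,
        evaluations_total=traj.evaluations,
        cpu_seconds=traj.cpu_seconds,
        success=traj.success,
        monitored_trajectory=mon,
        delta_n=delta_n(dn_series, delta_n_threshold) if dn_series else None,
        final_qi=traj.best_qi_per_generation[-1],
        final_candidate=best,
    )


def _pad_to(series: Sequence[float], length: int) -> np.ndarray:
    arr = np.asarray(series, dtype=float)
    if arr.size >= length:
        return arr[:length]
    return np.concatenate([arr, np.full(length - arr.size, arr[-1])])


def evolve_sigma_strategy(
    target: np.ndarray,
    partition: SigmaPartition,
    config: DEConfig,
    monitored_indices: Optional[np.ndarray] = None,
    delta_n_threshold: float = 0.01,
) -> RunResult:
    """Independent DE runs inside every sigma-factor block.

    Each block gets its own RNG substream derived from the config seed and
    its own stagnation/generation budget.  Success requires every block to
    succeed; the fraction of successful blocks is reported alongside.
    """
    target = np.asarray(target, dtype=float)
    if partition.n_genes != target.size:
        raise ValueError("partition does not cover the target length")
    mon = (np.asarray(monitored_indices, dtype=int)
           if monitored_indices is not None else None)

    block_trajs: list[Trajectory] = []
    best_full = np.empty(target.size)
    for b, block in enumerate(partition.blocks):
        block_mon = None
        if mon is not None:
            block_mon = np.intersect1d(mon, block)
        traj, best = run_de(
            target,
            block,
            config,
            rng=_strategy_rng(config.rng_seed, b),
            monitored_indices=block_mon if (block_mon is not None and block_mon.size) else None,
        )
        block_trajs.append(traj)
        best_full[block] = best

    n_gen = max(t.generations_run for t in block_trajs)
    sizes = np.asarray(partition.sizes, dtype=float)
    weights = sizes / sizes.sum()
    padded = np.vstack([
        _pad_to(t.best_qi_per_generation, n_gen + 1) for t in block_trajs
    ])
    combined_best = (weights[:, None] * padded).sum(axis=0)

    combined_mon: Optional[list[float]] = None
    if mon is not None and mon.size:
        mon_counts, mon_rows = [], []
        for t, block in zip(block_trajs, partition.blocks):
            k = np.intersect1d(mon, block).size
            if k and t.monitored_qi_per_generation:
                mon_counts.append(k)
                mon_rows.append(_pad_to(t.monitored_qi_per_generation, n_gen + 1))
        if mon_rows:
            w = np.asarray(mon_counts, dtype=float)
            w /= w.sum()
            combined_mon = (w[:, None] * np.vstack(mon_rows)).sum(axis=0).tolist()

    all_success = all(t.success for t in block_trajs)
    if all_success:
        reason = "success"
    elif any(t.stop_reason == "stagnation" for t in block_trajs):
        reason = "stagnation"
    else:
        reason = "max_generations"
    combined = Trajectory(
        best_qi_per_generation=combined_best.tolist(),
        generations_run=n_gen,
        evaluations=sum(t.evaluations for t in block_trajs),
        success=combined_best[-1] < config.qi_success_threshold,
        stop_reason=reason,
        cpu_seconds=sum(t.cpu_seconds for t in block_trajs),
        monitored_qi_per_generation=combined_mon,
    )
    combined.validate()

    dn_series = combined_mon if combined_mon else combined_best.tolist()
    return RunResult(
        strategy="sigma",
        trajectory=combined,
        generations_total=sum(t.generations_run for t in block_trajs),
        generations_max_block=n_gen,
        evaluations_total=combined.evaluations,
        cpu_seconds=combined.cpu_seconds,
        success=all_success,
        monitored_trajectory=combined_mon,
        delta_n=delta_n(dn_series, delta_n_threshold),
        final_qi=float(combined_best[-1]),
        final_candidate=best_full,
        partial_success_fraction=sum(t.success for t in block_trajs) / partition.n_blocks,
        block_trajectories=block_trajs,
    )


@dataclass
class ComparisonResult:
    """Paired whole-genome vs sigma-strategy comparison over replicates."""

    genome_runs: list[RunResult]
    sigma_runs: list[RunResult]
    fisher_p: Optional[float]
    summaries: dict = field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        return len(self.genome_runs)

    @property
    def success_table(self) -> list[list[int]]:
        """2x2 table [[genome succ, genome fail], [sigma succ, sigma fail]]."""
        gs = sum(r.success for r in self.genome_runs)
        ss = sum(r.success for r in self.sigma_runs)
        n = self.n_replicates
        return [[gs, n - gs], [ss, n - ss]]

    def to_records(self) -> list[dict]:
        rows = []
        for rep, (g, s) in enumerate(zip(self.genome_runs, self.sigma_runs)):
            for r in (g, s):
                rows.append({
                    "replicate": rep,
                    "strategy": r.strategy,
                    "generations_total": r.generations_total,
                    "generations_max_block": r.generations_max_block,
                    "evaluations_total": r.evaluations_total,
                    "cpu_seconds": r.cpu_seconds,
                    "success": r.success,
                    "final_qi": r.final_qi,
                    "delta_n": r.delta_n,
                })
        return rows


def _summaries(runs: list[RunResult]) -> dict:
    gens = np.asarray([r.generations_total for r in runs], dtype=float)
    evals = np.asarray([r.evaluations_total for r in runs], dtype=float)
    cpu = np.asarray([r.cpu_seconds for r in runs], dtype=float)
    return {
        "generations_median": float(np.median(gens)),
        "generations_mean": float(gens.mean()),
        "generations_sd": float(gens.std(ddof=1)) if len(runs) > 1 else 0.0,
        "evaluations_median": float(np.median(evals)),
        "evaluations_mean": float(evals.mean()),
        "evaluations_sd": float(evals.std(ddof=1)) if len(runs) > 1 else 0.0,
        "cpu_seconds_mean": float(cpu.mean()),
        "success_rate": float(np.mean([r.success for r in runs])),
    }


def compare_strategies(
    n_replicates: int,
    genome_size: int,
    partition_spec: Union[int, Sequence[int]],
    config: DEConfig,
) -> ComparisonResult:
    """Run both strategies on fresh targets and tabulate the outcomes.

    Each replicate draws a new uniform-random target and — when
    ``partition_spec`` is an integer block count — a new random partition;
    a list of sizes fixes the partition across replicates.  Both strategies
    see the same target.  Success counts go into a 2x2 table tested with
    Fisher's exact test (two-sided); with fewer than two replicates the
    p-value is reported as missing.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    master = np.random.default_rng(config.rng_seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=(n_replicates, 3))

    genome_runs: list[RunResult] = []
    sigma_runs: list[RunResult] = []
    for rep in range(n_replicates):
        t_seed, p_seed, r_seed = (int(s) for s in rep_seeds[rep])
        target = random_target(genome_size, t_seed)
        if isinstance(partition_spec, int):
            partition = random_partition(genome_size, partition_spec, p_seed)
        else:
            from .genome import make_partition

            partition = make_partition(genome_size, list(partition_spec))
        rep_config = DEConfig(**{**config.__dict__, "rng_seed": r_seed})
        genome_runs.append(evolve_genome_strategy(target, rep_config))
        sigma_runs.append(evolve_sigma_strategy(target, partition, rep_config))

    if n_replicates >= 2:
        table = [[sum(r.success for r in genome_runs),
                  n_replicates - sum(r.success for r in genome_runs)],
                 [sum(r.success for r in sigma_runs),
                  n_replicates - sum(r.success for r in sigma_runs)]]
        fisher_p = fisher_exact(*table[0], *table[1]).p_value
    else:
        fisher_p = None

    return ComparisonResult(
        genome_runs=genome_runs,
        sigma_runs=sigma_runs,
        fisher_p=fisher_p,
        summaries={
            "genome": _summaries(genome_runs),
            "sigma": _summaries(sigma_runs),
        },
    )
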