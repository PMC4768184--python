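"""Model/Results interface over the evolution simulator.

`TFEvolution` plays the role of a model object: it is built from the data
of one optimisation problem (a target transcription factor, optionally a
sigma partition and a monitored regulon) and `fit()` runs the differential
evolution, returning a `TFEvolutionResults` that carries the trajectory,
the bookkeeping and a printable `summary()`.  `StrategyComparison` is the
paired-design counterpart for whole-genome vs sigma-factor strategies.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .de import DEConfig
from .genome import GeneTable, SigmaPartition, partition_from_gene_table
from .strategies import (
    ComparisonResult,
    RunResult,
    compare_strategies,
    evolve_genome_strategy,
    evolve_sigma_strategy,
)
from .targets import target_from_expression

__all__ = ["TFEvolution", "TFEvolutionResults", "StrategyComparison", "StrategyComparisonResults"]


class TFEvolution:
    """Evolution of one target transcription factor.

    Parameters
    ----------
    target : array of float in [0, 1]
        Target expression vector, one entry per gene.
    partition : SigmaPartition, optional
        Required for ``strategy="sigma"``.
    strategy : {"genome", "sigma"}
    monitored_indices : array of int, optional
        Regulon whose QI is tracked alongside the genome-wide series.
    """

    def __init__(
        self,
        target: np.ndarray,
        partition: Optional[SigmaPartition] = None,
        strategy: str = "genome",
        monitored_indices: Optional[np.ndarray] = None,
    ):
        if strategy not in ("genome", "sigma"):
            raise ValueError("strategy must be 'genome' or 'sigma'")
        if strategy == "sigma" and partition is None:
            raise ValueError("sigma strategy requires a partition")
        self.target = np.asarray(target, dtype=float)
        if np.any((self.target < 0) | (self.target > 1)):
            raise ValueError("target entries must lie in [0, 1]")
        self.partition = partition
        self.strategy = strategy
        self.monitored_indices = (
            np.asarray(monitored_indices, dtype=int)
            if monitored_indices is not None else None
        )

    @classmethod
    def from_gene_table(
        cls,
        table: GeneTable,
        tf: Optional[str] = None,
        strategy: str = "sigma",
        label_order: Optional[Sequence[str]] = None,
    ) -> "TFEvolution":
        """Build the problem from a gene table's measured expression.

        Expression levels are max-normalised into the target vector; the
        sigma_label column provides the partition; if ``tf`` names a
        ``<tf>_regulon`` column, its members become the monitored regulon.
        """
        if "expression" not in table.df.columns or table.df["expression"].isna().all():
            raise ValueError("gene table carries no expression values")
        target = target_from_expression(table.df["expression"].to_numpy())
        partition = partition_from_gene_table(table, label_order=label_order)
        monitored = None
        if tf is not None:
            members = set(table.regulon_members(tf))
            monitored = np.flatnonzero(table.df["gene_id"].isin(members).to_numpy())
        return cls(target, partition, strategy, monitored)

    def fit(
        self,
        config: Optional[DEConfig] = None,
        delta_n_threshold: float = 0.01,
        **overrides,
    ) -> "TFEvolutionResults":
        """Run the optimisation and return the results object."""
        if config is None:
            config = DEConfig(**overrides)
        elif overrides:
            config = DEConfig(**{**config.__dict__, **overrides})
        if self.strategy == "genome":
            rr = evolve_genome_strategy(
                self.target, config,
                monitored_indices=self.monitored_indices,
                delta_n_threshold=delta_n_threshold,
            )
        else:
            rr = evolve_sigma_strategy(
                self.target, self.partition, config,
                monitored_indices=self.monitored_indices,
                delta_n_threshold=delta_n_threshold,
            )
        return TFEvolutionResults(self, config, rr)


class TFEvolutionResults:
    """Fitted results: trajectory, costs, success and the best candidate."""

    def __init__(self, model: TFEvolution, config: DEConfig, run_result: RunResult):
        self.model = model
        self.config = config
        self.run_result = run_result

    # convenience pass-throughs
    @property
    def trajectory(self):
        return self.run_result.trajectory

    @property
    def success(self) -> bool:
        return self.run_result.success

    @property
    def final_qi(self) -> float:
        return self.run_result.final_qi

    @property
    def delta_n(self) -> Optional[int]:
        return self.run_result.delta_n

    @property
    def best_candidate(self) -> Optional[np.ndarray]:
        return self.run_result.final_candidate

    def qi_frame(self) -> pd.DataFrame:
        """Per-generation best QI (and monitored QI when tracked)."""
        data = {"generation": np.arange(len(self.trajectory.best_qi_per_generation)),
                "best_qi": self.trajectory.best_qi_per_generation}
        mon = self.run_result.monitored_trajectory
        if mon:
            data["monitored_qi"] = mon
        return pd.DataFrame(data)

    def summary(self) -> str:
        rr = self.run_result
        lines = [
            "TF evolution results",
            "====================",
            f"strategy:              {rr.strategy}",
            f"genome size:           {self.model.target.size}",
            f"NP / CR / F:           {self.config.pop_size} / {self.config.cr} / {self.config.f}",
            f"success (QI < {self.config.qi_success_threshold:g}): {rr.success}",
            f"stop reason:           {rr.trajectory.stop_reason}",
            f"final QI:              {rr.final_qi:.6f}",
            f"generations (sum):     {rr.generations_total}",
            f"generations (max blk): {rr.generations_max_block}",
            f"coordinate evals:      {rr.evaluations_total}",
            f"cpu seconds:           {rr.cpu_seconds:.3f}",
        ]
        if rr.delta_n is not None:
            lines.append(f"delta_n (QI<0.01):     {rr.delta_n}")
        if rr.partial_success_fraction is not None:
            lines.append(f"blocks succeeded:      {rr.partial_success_fraction:.2%}")
        return "\n".join(lines)

    def plot_trajectory(self, ax=None):
        """Heat-map-style view of per-block QI over generations."""
        from .plot import plot_block_heatmap

        return plot_block_heatmap(self.run_result, ax=ax)


class StrategyComparison:
    """Paired comparison design: same targets, both strategies.

    ``partition_spec`` is either a block count (a fresh random partition
    per replicate) or an explicit list of block sizes (fixed partition).
    """

    def __init__(
        self,
        genome_size: int,
        partition_spec: Union[int, Sequence[int]] = 11,
        n_replicates: int = 20,
    ):
        if genome_size < 1:
            raise ValueError("genome_size must be positive")
        self.genome_size = int(genome_size)
        self.partition_spec = partition_spec
        self.n_replicates = int(n_replicates)

    def fit(self, config: Optional[DEConfig] = None, **overrides) -> "StrategyComparisonResults":
        if config is None:
            config = DEConfig(**overrides)
        elif overrides:
            config = DEConfig(**{**config.__dict__, **overrides})
        comp = compare_strategies(
            self.n_replicates, self.genome_size, self.partition_spec, config
        )
        return StrategyComparisonResults(self, config, comp)


class StrategyComparisonResults:
    def __init__(self, model: StrategyComparison, config: DEConfig, comparison: ComparisonResult):
        self.model = model
        self.config = config
        self.comparison = comparison

    @property
    def fisher_p(self) -> Optional[float]:
        return self.comparison.fisher_p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.comparison.to_records())

    def summary(self) -> str:
        s = self.comparison.summaries
        tbl = self.comparison.success_table
        lines = [
            "Strategy comparison",
            "===================",
            f"genome size:       {self.model.genome_size}",
            f"replicates:        {self.comparison.n_replicates}",
            f"success genome:    {tbl[0][0]}/{self.comparison.n_replicates}",
            f"success sigma:     {tbl[1][0]}/{self.comparison.n_replicates}",
            f"Fisher exact p:    {self.fisher_p if self.fisher_p is not None else 'NA'}",
        ]
        for strat in ("genome", "sigma"):
            st = s[strat]
            lines.append(
                f"{strat:>6}: median generations {st['generations_median']:.0f} "
                f"(sd {st['generations_sd']:.0f}), median evaluations "
                f"{st['evaluations_median']:.3g}, cpu {st['cpu_seconds_mean']:.2f}s"
            )
        return "\n".join(lines)
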