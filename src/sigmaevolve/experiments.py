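"""Reusable experiment designs: genome-size sweeps and hypothetical-TF sweeps.

These functions are the library form of the command-line experiments; they
return tidy DataFrames plus the attached statistics so results can be
written as TSV/JSON or inspected interactively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .de import DEConfig
from .genome import SigmaPartition, random_partition
from .stats import holm_bonferroni, rank_sum_test
from .strategies import (
    ComparisonResult,
    compare_strategies,
    evolve_genome_strategy,
    evolve_sigma_strategy,
)
from .targets import biased_regulon, hypothetical_tf

__all__ = [
    "genome_size_sweep",
    "hypothetical_sweep",
    "SweepResult",
]

REGULON_SIZES = (30, 200, 400, 800, 1200)
BIAS_MODES = ("small", "none", "large")


@dataclass
class SweepResult:
    """Per-run records plus the per-panel rank-sum tests of a sweep."""

    runs: pd.DataFrame
    tests: pd.DataFrame = field(default_factory=pd.DataFrame)
    comparisons: dict = field(default_factory=dict)


def genome_size_sweep(
    genome_sizes: Sequence[int],
    n_replicates: int,
    n_blocks: int,
    config: DEConfig,
) -> SweepResult:
    """Run the paired strategy comparison at several genome sizes.

    For each genome size a fresh set of targets and random partitions is
    drawn; success counts are compared with Fisher's exact test and
    generation/evaluation summaries are tabulated per size.
    """
    rows = []
    comparisons: dict[int, ComparisonResult] = {}
    for g_idx, g in enumerate(genome_sizes):
        cfg = DEConfig(**{**config.__dict__, "rng_seed": config.rng_seed + g_idx})
        comp = compare_strategies(n_replicates, int(g), n_blocks, cfg)
        comparisons[int(g)] = comp
        for rec in comp.to_records():
            rec["genome_size"] = int(g)
            rec["fisher_p"] = comp.fisher_p
            rows.append(rec)
    return SweepResult(runs=pd.DataFrame(rows), comparisons=comparisons)


def hypothetical_sweep(
    genome_size: int,
    n_blocks: int,
    config: DEConfig,
    regulon_sizes: Sequence[int] = REGULON_SIZES,
    bias_modes: Sequence[str] = BIAS_MODES,
    n_tfs: int = 10,
    bias_parameter: float = 0.5,
    delta_n_threshold: float = 0.01,
    strategies: Sequence[str] = ("genome", "sigma"),
    partition: Optional[SigmaPartition] = None,
) -> SweepResult:
    """Hypothetical-TF experiment over regulon size x sigma-usage bias classes.

    Builds ``len(regulon_sizes) * len(bias_modes)`` TF classes, ``n_tfs``
    targets per class, and evolves each target with the requested
    strategies.  Selection and termination use the whole transcriptome;
    the generations-to-threshold statistic delta_n is read off the QI
    series restricted to the TF's regulon.  Within every
    (strategy, regulon size) panel, bias modes are compared pairwise with
    the rank-sum test and Holm-corrected per panel.
    """
    master = np.random.default_rng(config.rng_seed)
    if partition is None:
        partition = random_partition(
            genome_size, n_blocks, int(master.integers(2**31 - 1))
        )
    elif partition.n_genes != genome_size:
        raise ValueError("partition size disagrees with genome_size")

    rows = []
    for size in regulon_sizes:
        for bias in bias_modes:
            for rep in range(n_tfs):
                reg_seed, tf_seed, run_seed = (
                    int(s) for s in master.integers(0, 2**31 - 1, size=3)
                )
                spec = biased_regulon(
                    partition, int(size), bias, bias_parameter, reg_seed
                )
                target, spec = hypothetical_tf(partition, spec, tf_seed)
                cfg = DEConfig(**{**config.__dict__, "rng_seed": run_seed})
                for strat in strategies:
                    if strat == "genome":
                        rr = evolve_genome_strategy(
                            target, cfg,
                            monitored_indices=spec.member_indices,
                            delta_n_threshold=delta_n_threshold,
                        )
                    elif strat == "sigma":
                        rr = evolve_sigma_strategy(
                            target, partition, cfg,
                            monitored_indices=spec.member_indices,
                            delta_n_threshold=delta_n_threshold,
                        )
                    else:
                        raise ValueError(f"unknown strategy {strat!r}")
                    rows.append({
                        "regulon_size": int(size),
                        "bias_mode": bias,
                        "replicate": rep,
                        "strategy": strat,
                        "delta_n": rr.delta_n,
                        "generations_total": rr.generations_total,
                        "evaluations_total": rr.evaluations_total,
                        "success": rr.success,
                        "final_qi": rr.final_qi,
                    })
    runs = pd.DataFrame(rows)
    runs["delta_n_threshold"] = delta_n_threshold

    tests = _bias_panel_tests(runs, strategies, regulon_sizes, bias_modes)
    return SweepResult(runs=runs, tests=tests)


def _bias_panel_tests(
    runs: pd.DataFrame,
    strategies: Sequence[str],
    regulon_sizes: Sequence[int],
    bias_modes: Sequence[str],
) -> pd.DataFrame:
    """Pairwise bias-mode comparisons of delta_n, Holm-corrected per panel."""
    out = []
    for strat in strategies:
        for size in regulon_sizes:
            panel = runs[(runs.strategy == strat) & (runs.regulon_size == size)]
            pairs, raw = [], []
            for a, b in combinations(bias_modes, 2):
                xa = panel.loc[panel.bias_mode == a, "delta_n"].dropna()
                xb = panel.loc[panel.bias_mode == b, "delta_n"].dropna()
                if len(xa) == 0 or len(xb) == 0:
                    continue
                res = rank_sum_test(xa, xb, alternative="two-sided")
                pairs.append((a, b, float(xa.median()), float(xb.median())))
                raw.append(res.p_value)
            adj = holm_bonferroni(raw) if raw else []
            for (a, b, ma, mb), p, ph in zip(pairs, raw, adj):
                out.append({
                    "strategy": strat,
                    "regulon_size": int(size),
                    "bias_a": a,
                    "bias_b": b,
                    "median_delta_n_a": ma,
                    "median_delta_n_b": mb,
                    "p_raw": p,
                    "p_holm": ph,
                })
    return pd.DataFrame(out)
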