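"""Target transcription factors and biased hypothetical regulons.

A transcription factor is abstracted as a target vector of per-gene
expression levels in [0, 1].  Targets are drawn uniformly at random,
derived from measured expression (max-normalised), or constructed as
"hypothetical" TFs whose regulon membership is deliberately biased toward
small or large sigma-factor blocks via geometric block weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genome import SigmaPartition

__all__ = [
    "RegulonSpec",
    "random_target",
    "target_from_expression",
    "biased_regulon",
    "hypothetical_tf",
]

BIAS_MODES = ("none", "small", "large")


@dataclass
class RegulonSpec:
    """A TF regulon: which genes the factor regulates and how it was drawn."""

    member_indices: np.ndarray
    size: int
    bias_mode: str = "none"
    bias_parameter: float = 0.5

    def __post_init__(self) -> None:
        self.member_indices = np.asarray(sorted(int(i) for i in self.member_indices), dtype=int)
        if self.member_indices.size != self.size:
            raise ValueError("size must equal the number of member indices")
        if self.bias_mode not in BIAS_MODES:
            raise ValueError(f"bias_mode must be one of {BIAS_MODES}")
        if not 0.0 < self.bias_parameter < 1.0:
            raise ValueError("bias_parameter must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "members": self.member_indices.tolist(),
            "size": self.size,
            "bias_mode": self.bias_mode,
            "bias_parameter": self.bias_parameter,
        }


def random_target(n_genes: int, rng_seed: int | np.random.Generator) -> np.ndarray:
    """Uniform(0, 1) expression level for each of ``n_genes`` genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    return rng.random(n_genes)


def target_from_expression(expression: np.ndarray) -> np.ndarray:
    """Max-normalise measured expression into a [0, 1] target vector."""
    expr = np.asarray(expression, dtype=float)
    if expr.ndim != 1:
        raise ValueError("expression must be one-dimensional")
    if np.any(expr < 0):
        raise ValueError("expression values must be nonnegative")
    m = expr.max() if expr.size else 0.0
    if m <= 0:
        raise ValueError("expression must contain at least one positive value")
    return expr / m


def _block_weights(partition: SigmaPartition, bias_mode: str, p: float) -> np.ndarray:
    """Geometric weight per block, ranked by block size.

    ``small`` ranks blocks ascending by size, ``large`` descending; rank k
    gets weight (1-p)^k * p, so the favoured end of the size spectrum
    dominates; ties in size are broken by declaration order (stable sort).
    """
    sizes = np.asarray(partition.sizes)
    if bias_mode == "small":
        order = np.argsort(sizes, kind="stable")
    elif bias_mode == "large":
        order = np.argsort(-sizes, kind="stable")
    else:
        raise ValueError(bias_mode)
    weights = np.empty(partition.n_blocks)
    weights[order] = (1.0 - p) ** np.arange(partition.n_blocks) * p
    return weights


def biased_regulon(
    partition: SigmaPartition,
    size: int,
    bias_mode: str = "none",
    bias_parameter: float = 0.5,
    rng_seed: int | np.random.Generator = 0,
    weight_per_gene: bool = False,
) -> RegulonSpec:
    """Draw a TF regulon of ``size`` genes with optional sigma-factor bias.

    ``none`` samples genes uniformly without replacement.  ``small`` /
    ``large`` assign each sigma block a geometric weight by its size rank
    (ascending / descending) and sample genes without replacement with
    probability proportional to their block's weight; as a block is
    exhausted the remaining weight renormalises automatically.  By default
    every gene carries its block's full weight; ``weight_per_gene=True``
    divides the block weight among the block's genes instead (so block
    *membership totals* rather than per-gene odds follow the geometric law).
    """
    if size > partition.n_genes:
        raise ValueError("regulon size cannot exceed the genome size")
    if size < 1:
        raise ValueError("regulon size must be >= 1")
    if bias_mode not in BIAS_MODES:
        raise ValueError(f"bias_mode must be one of {BIAS_MODES}")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    if bias_mode == "none":
        members = rng.choice(partition.n_genes, size=size, replace=False)
    else:
        bw = _block_weights(partition, bias_mode, bias_parameter)
        gene_w = bw[partition.block_of()]
        if weight_per_gene:
            gene_w = gene_w / np.asarray(partition.sizes)[partition.block_of()]
        # Efraimidis-Spirakis keys: top-k of U^(1/w) is a weighted sample
        # without replacement with sequential renormalisation semantics.
        # Work with log U / w — U^(1/w) underflows for the tiny weights the
        # geometric law produces at high ranks.
        keys = np.log(rng.random(partition.n_genes)) / gene_w
        members = np.argpartition(-keys, size - 1)[:size]
    return RegulonSpec(
        member_indices=members,
        size=size,
        bias_mode=bias_mode,
        bias_parameter=bias_parameter,
    )


def hypothetical_tf(
    partition: SigmaPartition,
    regulon_spec: RegulonSpec,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, RegulonSpec]:
    """Full-genome target for a hypothetical TF plus its regulon.

    All G expression levels are drawn uniform(0, 1) — evolution never takes
    place in isolation from the rest of the genome, so the whole
    transcriptome is optimised and terminates the run, while the regulon
    only determines which genes' quality index is monitored.
    """
    if regulon_spec.member_indices.size and (
        regulon_spec.member_indices.max() >= partition.n_genes
    ):
        raise ValueError("regulon indices exceed the genome size")
    target = random_target(partition.n_genes, rng_seed)
    return target, regulon_spec
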