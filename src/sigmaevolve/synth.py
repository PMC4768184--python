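"""Synthetic genomes, expression matrices and TF-mutant experiments.

Everything downstream — partitions, targets, the enrichment pipeline — can
be exercised without any external dataset.  The generative choices are
deliberately simple emulations of the statistical *structure* the analysis
assumes, not inferences about any real organism: log-normal expression with
a shared latent activity per sigma block (so within-block correlation
exceeds between-block correlation), and TF-mutant fold-change tables in
which true regulon members are at least two-fold regulated with small
adjusted p-values while background genes sit near fold change 1 with
uniform p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GeneTable, SigmaPartition, partition_from_gene_table
from .targets import RegulonSpec, biased_regulon

__all__ = [
    "SynthConfig",
    "DEFAULT_SIGMA_SIZES",
    "SIGMA_LABELS",
    "synth_genome",
    "synth_expression",
    "synth_tf_experiment",
]

# Illustrative sigma-regulon sizes for a ~6000-gene genome split into 11
# factors; chosen to span roughly a four-fold size range, not measured data.
DEFAULT_SIGMA_SIZES = (950, 820, 700, 640, 560, 500, 450, 400, 380, 330, 270)

SIGMA_LABELS = (
    "RpoN", "RpoS", "RpoH", "AlgU", "SigX", "FliA",
    "PvdS", "FecI", "FecI2", "FpvI", "RpoD",
)


@dataclass
class SynthConfig:
    """Knobs of the synthetic-data generator.

    ``modular_correlation`` in [0, 1] scales the shared per-block latent
    activity relative to the per-gene noise; 0 removes all block structure.
    ``noise_sd`` is the standard deviation, in log2 units, of the
    measurement noise added to true fold changes in TF-mutant experiments.
    """

    n_genes: int = 6000
    n_sigma: int = 11
    sigma_sizes: Optional[Sequence[int]] = None
    n_conditions: int = 14
    modular_correlation: float = 0.8
    regulon_specs: list = field(default_factory=list)
    noise_sd: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_sigma < 1 or self.n_conditions < 1:
            raise ValueError("sizes and counts must be positive")
        if not 0.0 <= self.modular_correlation <= 1.0:
            raise ValueError("modular_correlation must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.sigma_sizes is not None:
            sizes = [int(s) for s in self.sigma_sizes]
            if len(sizes) != self.n_sigma:
                raise ValueError("sigma_sizes length must equal n_sigma")
            if sum(sizes) != self.n_genes:
                raise ValueError("sigma_sizes must sum to n_genes")
            self.sigma_sizes = sizes

    def resolved_sizes(self) -> list[int]:
        if self.sigma_sizes is not None:
            return list(self.sigma_sizes)
        if (self.n_genes, self.n_sigma) == (6000, 11):
            return list(DEFAULT_SIGMA_SIZES)
        # spread as evenly as possible, remainder to the first blocks
        base, extra = divmod(self.n_genes, self.n_sigma)
        return [base + (1 if k < extra else 0) for k in range(self.n_sigma)]


def _labels(n_sigma: int) -> list[str]:
    if n_sigma <= len(SIGMA_LABELS):
        return list(SIGMA_LABELS[:n_sigma])
    return list(SIGMA_LABELS) + [f"sigma{k}" for k in range(len(SIGMA_LABELS), n_sigma)]


def synth_genome(config: SynthConfig) -> tuple[GeneTable, SigmaPartition]:
    """Gene table with randomly placed sigma assignments plus its partition.

    Gene ids follow the PA14-style ``PA14_xxxxx`` locus-tag convention.
    Block sizes are taken from the config; which genes land in which block
    is a random permutation, so different seeds give different assignments.
    """
    rng = np.random.default_rng(config.rng_seed)
    sizes = config.resolved_sizes()
    labels = _labels(config.n_sigma)
    per_gene = np.repeat(np.arange(config.n_sigma), sizes)
    per_gene = per_gene[rng.permutation(config.n_genes)]
    df = pd.DataFrame(
        {
            "gene_id": [f"PA14_{10 * (i + 1):05d}" for i in range(config.n_genes)],
            "sigma_label": [labels[b] for b in per_gene],
        }
    )
    table = GeneTable(df)
    partition = partition_from_gene_table(table, label_order=labels)
    return table, partition


def synth_expression(
    gene_table: GeneTable, partition: SigmaPartition, config: SynthConfig
) -> pd.DataFrame:
    """Condition x gene matrix of nonnegative expression values.

    Gene g in block b under condition c gets
    ``exp(modular_correlation * a[b, c] + sd_eps * eps)`` with a standard
    normal latent block activity ``a`` and independent gene-level noise, so
    within-block Pearson correlation across conditions exceeds
    between-block correlation whenever ``modular_correlation > 0``.
    """
    rng = np.random.default_rng([abs(int(config.rng_seed)), 1])
    block_act = rng.standard_normal((partition.n_blocks, config.n_conditions))
    eps = rng.standard_normal((partition.n_genes, config.n_conditions))
    b_of = partition.block_of()
    log_expr = config.modular_correlation * block_act[b_of] + 0.5 * eps
    mat = np.exp(log_expr).T  # conditions x genes
    return pd.DataFrame(
        mat,
        index=[f"cond{c + 1}" for c in range(config.n_conditions)],
        columns=gene_table.gene_ids.tolist(),
    )


def synth_tf_experiment(
    gene_table: GeneTable,
    partition: SigmaPartition,
    regulon_spec: RegulonSpec | dict,
    config: SynthConfig,
) -> tuple[pd.DataFrame, list[str]]:
    """Fold-change/adjusted-p table of a simulated TF-mutant profile.

    True regulon members receive log2 fold changes of magnitude
    ``1.5 + Exponential(0.5)`` with random sign and adjusted p-values
    uniform on (0, 0.01); background genes have true log2 fold change 0 and
    uniform p-values.  Gaussian measurement noise of ``config.noise_sd``
    log2 units is added to every gene, so at the default noise the two-fold
    + p <= 0.05 filter recovers the regulon with high but imperfect
    sensitivity.

    Returns the table (columns gene_id, fold_change, adjusted_p) and the
    true member gene ids.
    """
    if isinstance(regulon_spec, dict):
        spec = biased_regulon(
            partition,
            size=int(regulon_spec["size"]),
            bias_mode=regulon_spec.get("bias_mode", "none"),
            bias_parameter=float(regulon_spec.get("bias_parameter", 0.5)),
            rng_seed=np.random.default_rng([abs(int(config.rng_seed)), 2]),
        )
    else:
        spec = regulon_spec
    rng = np.random.default_rng([abs(int(config.rng_seed)), 3])
    n = partition.n_genes
    members = spec.member_indices

    true_lfc = np.zeros(n)
    magnitude = 1.5 + rng.exponential(scale=0.5, size=members.size)
    sign = rng.choice([-1.0, 1.0], size=members.size)
    true_lfc[members] = sign * magnitude

    observed_lfc = true_lfc + config.noise_sd * rng.standard_normal(n)
    padj = rng.uniform(0.0, 1.0, size=n)
    padj[members] = rng.uniform(0.0, 0.01, size=members.size)

    table = pd.DataFrame(
        {
            "gene_id": gene_table.gene_ids.tolist(),
            "fold_change": np.exp2(observed_lfc),
            "adjusted_p": padj,
        }
    )
    true_ids = gene_table.gene_ids.iloc[members].tolist()
    return table, true_ids
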