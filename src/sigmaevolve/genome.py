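"""Genome representation: gene tables and sigma-factor partitions.

The genome is an indexed set of ``G`` genes partitioned into ``S``
mutually exclusive sigma-factor regulons (blocks) that together cover the
whole genome.  Real bacterial genomes carry genes whose sigma-factor
assignment is ambiguous; those are collected into an implicit extra block
labelled ``"unassigned"`` so the partition remains covering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SigmaPartition",
    "GeneTable",
    "make_partition",
    "random_partition",
    "partition_from_gene_table",
    "read_gene_table",
    "write_gene_table",
]

UNASSIGNED = "unassigned"


@dataclass
class SigmaPartition:
    """Mutually exclusive, genome-covering grouping of gene indices.

    Attributes
    ----------
    n_genes : int
        Genome size G.
    blocks : list of int arrays
        Gene indices of each block, in declaration order.
    labels : list of str
        One identifier per block.
    """

    n_genes: int
    blocks: list[np.ndarray]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.blocks = [np.asarray(sorted(int(i) for i in b), dtype=int) for b in self.blocks]
        if not self.labels:
            self.labels = [f"sigma{k}" for k in range(len(self.blocks))]
        self.validate()

    @property
    def sizes(self) -> list[int]:
        return [int(b.size) for b in self.blocks]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.blocks) < 1:
            raise ValueError("a partition needs at least one block")
        if len(self.labels) != len(self.blocks):
            raise ValueError("labels and blocks must have equal length")
        concat = np.concatenate(self.blocks) if self.blocks else np.array([], dtype=int)
        if concat.size != self.n_genes:
            raise ValueError(
                f"block sizes sum to {concat.size}, expected n_genes={self.n_genes}"
            )
        seen = np.sort(concat)
        if not np.array_equal(seen, np.arange(self.n_genes)):
            raise ValueError("blocks must be disjoint and cover 0..n_genes-1")
        for b in self.blocks:
            if b.size < 1:
                raise ValueError("every block must contain at least one gene")

    def block_of(self) -> np.ndarray:
        """Array mapping each gene index to the index of its block."""
        out = np.empty(self.n_genes, dtype=int)
        for k, b in enumerate(self.blocks):
            out[b] = k
        return out

    def to_json(self, path: str | Path) -> None:
        obj = {
            "labels": self.labels,
            "sizes": self.sizes,
            "block_members": [b.tolist() for b in self.blocks],
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "SigmaPartition":
        obj = json.loads(Path(path).read_text())
        members = [np.asarray(b, dtype=int) for b in obj["block_members"]]
        n = int(sum(len(b) for b in members))
        return cls(n_genes=n, blocks=members, labels=list(obj["labels"]))


def make_partition(
    n_genes: int,
    sizes: Sequence[int],
    labels: Optional[Sequence[str]] = None,
) -> SigmaPartition:
    """Partition ``n_genes`` into contiguous blocks of the given sizes.

    Blocks are contiguous index ranges in declaration order, the natural
    layout for simulated genomes; non-contiguous assignments (real data)
    go through :func:`partition_from_gene_table`.
    """
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("all block sizes must be >= 1")
    if sum(sizes) != n_genes:
        raise ValueError(f"sizes sum to {sum(sizes)}, expected n_genes={n_genes}")
    bounds = np.cumsum([0] + sizes)
    blocks = [np.arange(bounds[k], bounds[k + 1]) for k in range(len(sizes))]
    return SigmaPartition(n_genes=n_genes, blocks=blocks,
                          labels=list(labels) if labels else [])


def random_partition(
    n_genes: int,
    n_blocks: int,
    rng_seed: int,
    sizes_pool: Optional[Sequence[int]] = None,
    labels: Optional[Sequence[str]] = None,
) -> SigmaPartition:
    """Partition with randomly drawn block sizes.

    By default block sizes come from placing ``n_blocks - 1`` uniform cut
    points among the ``n_genes - n_blocks`` "free" genes and adding one to
    every block, which guarantees each block holds at least one gene.  If
    ``sizes_pool`` is given (e.g. a list of measured regulon sizes summing
    to ``n_genes``) the pool is randomly permuted and used as the sizes
    instead — the two readings of "randomly attributed sizes".
    """
    if n_blocks > n_genes:
        raise ValueError("n_blocks cannot exceed n_genes")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(rng_seed)
    if sizes_pool is not None:
        sizes = [int(s) for s in rng.permutation(np.asarray(sizes_pool, dtype=int))]
    else:
        free = n_genes - n_blocks
        cuts = np.sort(rng.integers(0, free + 1, size=n_blocks - 1))
        sizes = (np.diff(np.concatenate(([0], cuts, [free]))) + 1).tolist()
    return make_partition(n_genes, sizes, labels=labels)


class GeneTable:
    """Per-gene annotation table backed by a pandas DataFrame.

    Columns: ``gene_id`` (unique strings), ``sigma_label`` (sigma-factor
    assignment or ``"unassigned"``), optional ``expression`` (nonnegative
    reals), and any number of boolean ``<tf>_regulon`` membership columns.
    """

    REQUIRED = ("gene_id", "sigma_label")

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True).copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"gene table missing required column {col!r}")
        dup = df["gene_id"][df["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene_id: {dup.iloc[0]!r}")
        df["sigma_label"] = df["sigma_label"].fillna(UNASSIGNED)
        if "expression" in df.columns:
            expr = pd.to_numeric(df["expression"], errors="raise")
            bad = expr.dropna() < 0
            if bad.any():
                row = int(bad[bad].index[0])
                raise ValueError(
                    f"negative expression for gene {df['gene_id'].iloc[row]!r} (row {row})"
                )
            df["expression"] = expr
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneTable):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def gene_ids(self) -> pd.Series:
        return self.df["gene_id"]

    @property
    def regulon_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.endswith("_regulon")]

    def regulon_members(self, tf: str) -> list[str]:
        """Gene ids flagged as members of ``<tf>_regulon``."""
        col = f"{tf}_regulon"
        if col not in self.df.columns:
            raise KeyError(f"no regulon column for TF {tf!r}")
        mask = self.df[col].astype(bool)
        return self.df.loc[mask, "gene_id"].tolist()


def partition_from_gene_table(
    table: GeneTable, label_order: Optional[Sequence[str]] = None
) -> SigmaPartition:
    """Build a covering partition from a table's sigma_label column.

    Genes labelled ``"unassigned"`` form one extra block so the partition
    still covers the genome.
    """
    labels_present = [l for l in table.df["sigma_label"].unique() if l != UNASSIGNED]
    order = list(label_order) if label_order else sorted(labels_present)
    missing = set(labels_present) - set(order)
    if missing:
        raise ValueError(f"label_order missing sigma labels: {sorted(missing)}")
    if (table.df["sigma_label"] == UNASSIGNED).any():
        order = order + [UNASSIGNED]
    blocks = [np.flatnonzero((table.df["sigma_label"] == lab).to_numpy()) for lab in order]
    keep = [(lab, b) for lab, b in zip(order, blocks) if b.size > 0]
    return SigmaPartition(
        n_genes=len(table),
        blocks=[b for _, b in keep],
        labels=[lab for lab, _ in keep],
    )


def read_gene_table(path: str | Path) -> GeneTable:
    """Read a tab-separated gene table; raises naming the offending line."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sigma_label": str})
    except Exception as exc:  # pandas errors carry the line number
        raise ValueError(f"malformed gene table {path}: {exc}") from exc
    try:
        return GeneTable(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)
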