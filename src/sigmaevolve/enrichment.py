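"""Enrichment-factor statistic and the regulated-gene filter.

The enrichment factor (EF) compares the share of a category (a sigma-factor
regulon, a functional class, ...) among a detected gene set with its share
of the annotated genome:

    EF = (k_detected / n_detected) / (K_annotated / N_annotated)

EF >= 1.5 is called over-representation and EF <= 0.66 under-representation
(configurable).  Upstream of the EF sits the regulated-gene filter: a gene
counts as differentially expressed when it is at least two-fold up- or
down-regulated and its FDR-adjusted p-value is at most 0.05; the
fold-change/adjusted-p table itself comes from a differential-expression
fit performed elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import UNASSIGNED, GeneTable

__all__ = [
    "EnrichmentResult",
    "enrichment_factor",
    "classify_enrichment",
    "regulated_gene_filter",
    "regulon_composition",
]

OVER_THRESHOLD = 1.5
UNDER_THRESHOLD = 0.66


@dataclass
class EnrichmentResult:
    category: str
    k_detected: int
    n_detected: int
    K_annotated: int
    N_annotated: int
    ef: float
    call: str

    def __post_init__(self) -> None:
        if not 0 <= self.k_detected <= min(self.n_detected, self.K_annotated):
            raise ValueError("inconsistent enrichment counts")


def enrichment_factor(
    k_detected: int, n_detected: int, K_annotated: int, N_annotated: int
) -> float:
    """Ratio of the category's detected share to its annotated share."""
    counts = (k_detected, n_detected, K_annotated, N_annotated)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValueError("counts must be nonnegative integers")
    if n_detected <= 0 or K_annotated <= 0 or N_annotated <= 0:
        raise ValueError("n_detected, K_annotated and N_annotated must be positive")
    if k_detected > n_detected or k_detected > K_annotated or K_annotated > N_annotated:
        raise ValueError("inconsistent counts")
    return (k_detected / n_detected) / (K_annotated / N_annotated)


def classify_enrichment(
    ef: float,
    over_threshold: float = OVER_THRESHOLD,
    under_threshold: float = UNDER_THRESHOLD,
) -> str:
    """'over' iff EF >= 1.5, 'under' iff EF <= 0.66, else 'none'."""
    if ef < 0:
        raise ValueError("EF must be nonnegative")
    if ef >= over_threshold:
        return "over"
    if ef <= under_threshold:
        return "under"
    return "none"


def regulated_gene_filter(
    fold_changes: Sequence[float],
    adjusted_p: Sequence[float],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> np.ndarray:
    """Indices of genes passing the differential-expression filter.

    A gene passes when its fold change is >= fc_threshold (up) or
    <= 1/fc_threshold (down) and its FDR-adjusted p-value is <= alpha.
    Fold changes are ratios and must be strictly positive.
    """
    fc = np.asarray(fold_changes, dtype=float)
    p = np.asarray(adjusted_p, dtype=float)
    if fc.shape != p.shape:
        raise ValueError("fold_changes and adjusted_p must have equal length")
    if np.any(fc <= 0):
        raise ValueError("fold changes must be strictly positive")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("adjusted p-values must lie in [0, 1]")
    regulated = (fc >= fc_threshold) | (fc <= 1.0 / fc_threshold)
    return np.flatnonzero(regulated & (p <= alpha))


def regulon_composition(
    tf_regulon: Iterable[str],
    gene_table: GeneTable,
    include_unassigned_in_totals: bool = True,
    over_threshold: float = OVER_THRESHOLD,
    under_threshold: float = UNDER_THRESHOLD,
) -> list[EnrichmentResult]:
    """EF of every sigma-factor regulon within a TF's regulated gene set.

    ``tf_regulon`` is a collection of gene ids drawn from ``gene_table``.
    Genes with no sigma assignment form no category of their own but, by
    default, still count in the detected-set and genome totals (mirroring
    genomes with ambiguously assigned genes); setting
    ``include_unassigned_in_totals=False`` restricts both totals to genes
    with a sigma assignment.
    """
    regulon = list(dict.fromkeys(tf_regulon))
    df = gene_table.df
    known = set(df["gene_id"])
    for g in regulon:
        if g not in known:
            raise KeyError(f"regulon gene {g!r} absent from the gene table")

    in_regulon = df["gene_id"].isin(regulon)
    assigned = df["sigma_label"] != UNASSIGNED
    if include_unassigned_in_totals:
        n_detected = int(in_regulon.sum())
        N_annotated = len(df)
    else:
        n_detected = int((in_regulon & assigned).sum())
        N_annotated = int(assigned.sum())
    if n_detected == 0:
        raise ValueError("detected gene set is empty")

    results = []
    categories = [l for l in pd.unique(df["sigma_label"]) if l != UNASSIGNED]
    for cat in categories:
        in_cat = df["sigma_label"] == cat
        k = int((in_regulon & in_cat).sum())
        K = int(in_cat.sum())
        ef = enrichment_factor(k, n_detected, K, N_annotated)
        results.append(
            EnrichmentResult(
                category=str(cat),
                k_detected=k,
                n_detected=n_detected,
                K_annotated=K,
                N_annotated=N_annotated,
                ef=ef,
                call=classify_enrichment(ef, over_threshold, under_threshold),
            )
        )
    return results


def composition_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flatten enrichment results to a tidy frame (category, k, n, K, N, EF, call)."""
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "k_detected": r.k_detected,
                "n_detected": r.n_detected,
                "K_annotated": r.K_annotated,
                "N_annotated": r.N_annotated,
                "EF": r.ef,
                "call": r.call,
            }
            for r in results
        ]
    )
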