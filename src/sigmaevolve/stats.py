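"""Nonparametric comparison statistics used throughout the experiments.

Thin, validated wrappers around scipy/statsmodels: Fisher's exact test for
2x2 success tables, the Wilcoxon-Mann-Whitney rank-sum test for generation
counts between TF classes (exact for small tie-free samples, normal
approximation with tie correction otherwise), the Wilcoxon signed-rank test
for paired strategy comparisons, and the Holm-Bonferroni step-down
correction for families of comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "fisher_exact",
    "rank_sum_test",
    "signed_rank_test",
    "holm_bonferroni",
]

ALTERNATIVES = ("two-sided", "less", "greater")

# combined sample size up to which the tie-free rank-sum null is enumerated
# exactly rather than normal-approximated
EXACT_RANKSUM_MAX_N = 12


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    alternative: str
    exact: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError("p-value out of [0, 1]")
        self.p_value = min(self.p_value, 1.0)


def _check_alternative(alternative: str) -> None:
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")


def fisher_exact(
    a: int, b: int, c: int, d: int, alternative: str = "two-sided"
) -> TestResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]]."""
    _check_alternative(alternative)
    counts = [a, b, c, d]
    if any(int(x) != x or x < 0 for x in counts):
        raise ValueError("counts must be nonnegative integers")
    if sum(counts) == 0:
        raise ValueError("degenerate table: all counts zero")
    res = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="fisher_exact",
        alternative=alternative,
        exact=True,
    )


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon-Mann-Whitney test; statistic is the Mann-Whitney U of x.

    The exact permutation null is used when the combined sample size is at
    most 12 and the data carry no ties; otherwise the normal approximation
    with tie correction (and continuity correction) is applied.  The
    ``exact`` flag on the result records which route was taken.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    exact = no_ties and combined.size <= EXACT_RANKSUM_MAX_N
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="wilcoxon_mann_whitney",
        alternative=alternative,
        exact=exact,
    )


def signed_rank_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon signed-rank test for paired samples (x_i vs y_i)."""
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or x.size != y.size:
        raise ValueError("paired samples must be non-empty and equally long")
    if np.allclose(x, y):
        raise ValueError("all paired differences are zero")
    res = sps.wilcoxon(x, y, alternative=alternative)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="wilcoxon_signed_rank",
        alternative=alternative,
        exact=False,
    )


def holm_bonferroni(p_values: Sequence[float]) -> list[float]:
    """Holm-Bonferroni step-down adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1].tolist()
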