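import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigmaevolve.enrichment import (
    classify_enrichment,
    composition_table,
    enrichment_factor,
    regulated_gene_filter,
    regulon_composition,
)
from sigmaevolve.genome import GeneTable


class TestEnrichmentFactor:
    def test_hand_computed_ratio(self):
        assert enrichment_factor(10, 40, 100, 1000) == pytest.approx(2.5)

    def test_matching_composition_gives_one(self):
        assert enrichment_factor(4, 40, 100, 1000) == pytest.approx(1.0)

    def test_empty_intersection_gives_zero(self):
        assert enrichment_factor(0, 40, 100, 1000) == 0.0

    @pytest.mark.parametrize(
        "counts", [(1, 0, 5, 10), (1, 5, 0, 10), (1, 5, 10, 0), (6, 5, 10, 20)]
    )
    def test_invalid_counts_rejected(self, counts):
        with pytest.raises(ValueError):
            enrichment_factor(*counts)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        k=st.integers(0, 10),
        extra_n=st.integers(0, 10),
        extra_k=st.integers(0, 10),
        extra_nn=st.integers(0, 10),
        scale=st.integers(1, 7),
    )
    def test_invariant_under_count_scaling(self, k, extra_n, extra_k, extra_nn, scale):
        n = k + extra_n + 1
        K = k + extra_k + 1
        N = K + extra_nn + n
        base = enrichment_factor(k, n, K, N)
        scaled = enrichment_factor(k * scale, n * scale, K * scale, N * scale)
        assert scaled == pytest.approx(base)


class TestClassification:
    @pytest.mark.parametrize(
        "ef,call",
        [
            (1.63, "over"),   # RpoS share of a quorum-sensing regulator's profile
            (3.44, "over"),   # FliA share of a flagellar regulator's profile
            (2.12, "over"),
            (1.5, "over"),    # threshold is inclusive
            (1.22, "none"),   # a sub-threshold "preference"
            (1.27, "none"),
            (0.66, "under"),  # inclusive on the under side too
            (0.5, "under"),
            (1.0, "none"),
        ],
    )
    def test_threshold_calls(self, ef, call):
        assert classify_enrichment(ef) == call

    def test_custom_thresholds(self):
        assert classify_enrichment(1.3, over_threshold=1.25) == "over"

    def test_negative_ef_rejected(self):
        with pytest.raises(ValueError):
            classify_enrichment(-0.1)


class TestRegulatedGeneFilter:
    def test_two_fold_up_with_small_p_included(self):
        assert 0 in regulated_gene_filter([4.0], [0.01])

    def test_insufficient_fold_change_excluded(self):
        assert regulated_gene_filter([1.5], [0.001]).size == 0

    def test_down_regulated_branch(self):
        assert 0 in regulated_gene_filter([0.4], [0.04])

    def test_boundary_values_inclusive(self):
        idx = regulated_gene_filter([2.0, 0.5, 2.0], [0.05, 0.05, 0.051])
        assert idx.tolist() == [0, 1]

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValueError):
            regulated_gene_filter([0.0, 2.0], [0.01, 0.01])


def _table(labels):
    return GeneTable(
        pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(labels))],
                "sigma_label": labels,
            }
        )
    )


class TestRegulonComposition:
    def test_regulon_inside_one_small_block(self):
        # category holds 10% of the genome; a regulon drawn entirely from it
        # has EF = 1 / 0.1 = 10
        labels = ["sA"] * 10 + ["sB"] * 90
        table = _table(labels)
        results = regulon_composition([f"g{i}" for i in range(5)], table)
        by_cat = {r.category: r for r in results}
        assert by_cat["sA"].ef == pytest.approx(10.0)
        assert by_cat["sA"].call == "over"
        assert by_cat["sB"].ef == 0.0

    def test_weighted_mean_ef_is_one_on_partitioning_categories(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["sA", "sB", "sC"], size=200, p=[0.5, 0.3, 0.2])
        table = _table(labels)
        regulon = [f"g{i}" for i in rng.choice(200, 40, replace=False)]
        results = regulon_composition(regulon, table)
        weighted = sum((r.K_annotated / r.N_annotated) * r.ef for r in results)
        assert weighted == pytest.approx(1.0)

    def test_unassigned_counts_in_totals_not_categories(self):
        labels = ["sA"] * 20 + ["unassigned"] * 20 + ["sB"] * 60
        table = _table(labels)
        regulon = [f"g{i}" for i in range(10)] + [f"g{i}" for i in range(20, 30)]
        results = regulon_composition(regulon, table)
        cats = {r.category for r in results}
        assert cats == {"sA", "sB"}
        assert all(r.n_detected == 20 for r in results)  # unassigned kept in n
        assert all(r.N_annotated == 100 for r in results)
        restricted = regulon_composition(
            regulon, table, include_unassigned_in_totals=False
        )
        assert all(r.n_detected == 10 for r in restricted)
        assert all(r.N_annotated == 80 for r in restricted)

    def test_unknown_gene_named_in_error(self):
        table = _table(["sA", "sB"])
        with pytest.raises(KeyError, match="ghost"):
            regulon_composition(["g0", "ghost"], table)

    def test_composition_table_is_tidy(self):
        table = _table(["sA"] * 4 + ["sB"] * 6)
        df = composition_table(regulon_composition(["g0", "g5"], table))
        assert list(df.columns) == [
            "category", "k_detected", "n_detected", "K_annotated",
            "N_annotated", "EF", "call",
        ]
        assert len(df) == 2
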