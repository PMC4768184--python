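import numpy as np
import pandas as pd
import pytest

from sigmaevolve.genome import GeneTable, make_partition


@pytest.fixture
def small_partition():
    """60 genes in 4 blocks of uneven size."""
    return make_partition(60, [10, 25, 5, 20], labels=["sA", "sB", "sC", "sD"])


@pytest.fixture
def gene_table_df():
    """A 12-gene table with sigma labels, expression and one TF regulon."""
    rng = np.random.default_rng(7)
    labels = ["RpoS"] * 4 + ["FliA"] * 3 + ["unassigned"] * 2 + ["RpoN"] * 3
    return pd.DataFrame(
        {
            "gene_id": [f"PA14_{i:05d}" for i in range(12)],
            "sigma_label": labels,
            "expression": np.round(rng.uniform(0.5, 50.0, 12), 3),
            "lasr_regulon": [True, True, False, False, True, False,
                             False, False, False, True, False, False],
        }
    )


@pytest.fixture
def gene_table(gene_table_df):
    return GeneTable(gene_table_df)
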