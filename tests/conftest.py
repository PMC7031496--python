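import numpy as np
import pandas as pd
import pytest

from culprit import ExpressionCohort


def make_cohort(values, gene_ids=None, sample_ids=None, groups=None) -> ExpressionCohort:
    """Build a small ExpressionCohort from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    groups = groups or ["grp"] * n_samples
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                      columns=pd.Index(sample_ids, name="sample_id"))
    return ExpressionCohort(df, pd.Series(groups, index=df.columns))


@pytest.fixture
def rng():
    return np.random.default_rng(20501)


@pytest.fixture
def small_cohort():
    """3 genes x 4 samples, one group."""
    return make_cohort([[1.0, 2.0, 3.0, 4.0],
                        [4.0, 3.0, 2.0, 1.0],
                        [5.0, 5.0, 5.0, 5.0]])
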