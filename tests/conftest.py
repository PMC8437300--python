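import numpy as np
import pytest

from iusmmt.core_data import (CovariateTable, GeneDataset,
                              MethylationBlock, standardize)
from iusmmt.simulator import (apply_censoring, simulate_expression,
                              simulate_methylation_block,
                              simulate_survival)


def make_gene_dataset(n=60, k=5, tau2=0.0, beta=0.0, tau3=0.02,
                      seed=0, raw_expression=False, censor=0.5):
    """One synthetic gene dataset built from the simulator primitives."""
    rng = np.random.default_rng(seed)
    M = simulate_methylation_block(n, rng, k=k, gene_id=f"g{seed}")
    x1 = standardize(rng.standard_normal(n))
    x2 = standardize(rng.integers(1, 6, size=n).astype(float))
    X = np.column_stack([x1, x2])
    G = simulate_expression(M.values, X, tau2, rng)
    t = simulate_survival(M.values, G, X, beta, tau3, rng)
    outcome = apply_censoring(t, censor, rng)
    expr = G if raw_expression else standardize(G)
    return GeneDataset(methylation=M, expression=expr, outcome=outcome,
                       covariates=CovariateTable(values=X,
                                                 names=["x1", "x2"]))


@pytest.fixture
def toy_gene():
    return make_gene_dataset(n=60, k=5, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
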