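import numpy as np
import pandas as pd
import pytest

from pcwnet.exprio import DiscreteMatrix, ExpressionMatrix, SeedSet, STAGES


def make_discrete(array, q=0.25):
    a = np.asarray(array, dtype=np.int8)
    df = pd.DataFrame(
        a,
        index=[f"g{i}" for i in range(a.shape[0])],
        columns=[f"c{j}" for j in range(a.shape[1])],
    )
    return DiscreteMatrix(df, q=q)


def make_expression(array, genes=None, conds=None):
    a = np.asarray(array, dtype=float)
    genes = genes or [f"g{i}" for i in range(a.shape[0])]
    conds = conds or [f"c{j}" for j in range(a.shape[1])]
    return ExpressionMatrix(pd.DataFrame(a, index=genes, columns=conds))


@pytest.fixture
def standard_instance():
    """The standard planted-bicluster benchmark (one fixed seed)."""
    from pcwnet.synthdata import SynthConfig, generate_expression, generate_seed_labels

    cfg = SynthConfig(rng_seed=0)
    expr, truth = generate_expression(cfg)
    seeds = generate_seed_labels(truth, seeds_per_bicluster=5, rng_seed=0)
    return expr, truth, seeds


def seed_set(genes, stage=STAGES[0]):
    return SeedSet({g: stage for g in genes})
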