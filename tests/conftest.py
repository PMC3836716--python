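import numpy as np
import pytest

from pathsgl.data import GenotypeMatrix, PhenotypeTable
from pathsgl.mapping import PathwayCollection
from pathsgl.sgl import SGLProblem


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_problem(
    rng,
    n=60,
    groups=((0, 10), (10, 20), (20, 30)),
    beta=None,
    noise=1.0,
    overlap_groups=None,
):
    """Random standardised problem with the given group index ranges."""
    if overlap_groups is not None:
        group_arrays = [np.asarray(g, dtype=np.int64) for g in overlap_groups]
    else:
        group_arrays = [np.arange(a, b) for a, b in groups]
    P = int(max(g.max() for g in group_arrays)) + 1
    X = rng.standard_normal((n, P))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    b = np.zeros(P)
    if beta:
        for j, v in beta.items():
            b[j] = v
    y = X @ b + noise * rng.standard_normal(n)
    y -= y.mean()
    coll = PathwayCollection(group_arrays, [f"pw{i}" for i in range(len(group_arrays))])
    return SGLProblem(X, y, coll)


@pytest.fixture
def small_genotypes(rng):
    maf = rng.uniform(0.1, 0.5, size=30)
    G = rng.binomial(2, maf, size=(80, 30)).astype(float)
    return GenotypeMatrix(G, [f"s{j}" for j in range(30)])


@pytest.fixture
def small_phenotype(rng, small_genotypes):
    y = rng.standard_normal(small_genotypes.n_samples)
    return PhenotypeTable(y - y.mean())
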