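import numpy as np
import pytest

from specfp import ModelSpec, sample_graph_set, takahashi_test


@pytest.fixture(scope="session")
def er_pair_factory():
    """Factory for pairs of Erdős–Rényi graph sets with disjoint seed streams."""

    def make(rep, p_a=0.1, p_b=0.1, n=50, na=20, nb=20):
        a = sample_graph_set(
            ModelSpec("erdos_renyi", n=n, n_graphs=na, p=p_a, seed=1000 + rep), label="a"
        )
        b = sample_graph_set(
            ModelSpec("erdos_renyi", n=n, n_graphs=nb, p=p_b, seed=5000 + rep), label="b"
        )
        return a, b

    return make


@pytest.fixture(scope="session")
def null_pvalues_200(er_pair_factory):
    """200 two-set permutation-test p-values under a true null.

    Both sets are drawn from the same G(50, 0.1) process (20 graphs each,
    200 permutations); used both for type-I calibration and for the
    uniformity of null p-values.
    """
    pvals = []
    for rep in range(200):
        a, b = er_pair_factory(rep)
        pvals.append(takahashi_test(a, b, n_permutations=200, seed=rep + 1).p_value)
    return np.array(pvals)
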