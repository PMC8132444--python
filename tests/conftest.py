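import numpy as np
import pytest

from isclust import SyntheticSpec, preprocess, simulate_expression


@pytest.fixture(scope="session")
def planted_default():
    """The documented reference fixture: 3 planted types, 150 cells, 500 genes."""
    spec = SyntheticSpec()
    expr, labels = simulate_expression(spec)
    return spec, expr, labels


@pytest.fixture(scope="session")
def planted_normalized(planted_default):
    spec, expr, labels = planted_default
    return preprocess(expr), labels


@pytest.fixture(scope="session")
def planted_small():
    """A fast 60-cell fixture for end-to-end tests that loop."""
    spec = SyntheticSpec(n_cells=60, n_genes=200, seed=7)
    expr, labels = simulate_expression(spec)
    return preprocess(expr), labels


def random_partition_pair(rng, n_max=30):
    n = int(rng.integers(2, n_max + 1))
    ku = int(rng.integers(1, min(n, 5) + 1))
    kv = int(rng.integers(1, min(n, 5) + 1))
    return rng.integers(0, ku, size=n).tolist(), rng.integers(0, kv, size=n).tolist()
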