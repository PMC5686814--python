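import numpy as np
import pytest

from tadcluster.features import FeatureTable, build_diagonal_features
from tadcluster.simulate import default_benchmark_spec, generate_block_matrix


@pytest.fixture
def benchmark_clean():
    """Zero-noise 30-bin five-domain matrix with its planted truth."""
    return generate_block_matrix(default_benchmark_spec(seed=7, noise_sd=0.0))


@pytest.fixture
def benchmark_noisy():
    """Noisy (sd = 1) 30-bin five-domain matrix with its planted truth."""
    return generate_block_matrix(default_benchmark_spec(seed=7, noise_sd=1.0))


@pytest.fixture
def benchmark_features(benchmark_clean):
    m, _ = benchmark_clean
    return build_diagonal_features(m)


def random_instance(rng, n_max=20, k_max=5, dim=4):
    """A random labelled point set for oracle-equivalence checks."""
    n = int(rng.integers(6, n_max + 1))
    k = int(rng.integers(2, min(k_max, n // 2) + 1))
    x = rng.normal(size=(n, dim))
    # every cluster non-empty
    labels = np.concatenate([np.arange(k), rng.integers(0, k, size=n - k)])
    rng.shuffle(labels)
    f = FeatureTable(vectors=x, bin_index=np.arange(n), n_bins=n)
    return f, labels.astype(int), k
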