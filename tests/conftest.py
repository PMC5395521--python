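import numpy as np
import pytest

from simboost import AffinityMatrix, SimilarityMatrix, SyntheticConfig, generate_dataset


@pytest.fixture
def toy_affinity():
    """3 drugs x 3 targets with two unobserved cells."""
    values = np.array([
        [1.0, 2.0, np.nan],
        [4.0, np.nan, 6.0],
        [7.0, 8.0, 9.0],
    ])
    observed = ~np.isnan(values)
    return AffinityMatrix(values, observed, ["dA", "dB", "dC"], ["t1", "t2", "t3"])


@pytest.fixture
def toy_similarity():
    values = np.array([
        [1.0, 0.8, 0.2],
        [0.8, 1.0, 0.6],
        [0.2, 0.6, 1.0],
    ])
    return SimilarityMatrix(values, ["a", "b", "c"])


@pytest.fixture(scope="session")
def small_dataset():
    """Session-cached small synthetic dataset for the slower integration tests."""
    cfg = SyntheticConfig(n_drugs=30, n_targets=20, density=0.5,
                          obs_heterogeneity=0.5, seed=11)
    return generate_dataset(cfg)
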