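import numpy as np
import pytest

from epiharmony import GenotypeDataset, interaction_model, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20160325)


@pytest.fixture
def tiny_dataset():
    """Four individuals, two SNPs, hand-countable."""
    return GenotypeDataset(
        genotypes=np.array([[0, 0], [0, 0], [2, 2], [1, 1]]),
        phenotype=np.array([0, 0, 1, 1]),
        snp_ids=["X1", "X2"],
    )


@pytest.fixture(scope="session")
def strong_dataset():
    """400+400 samples, 20 SNPs, strong pure-interaction causal pair."""
    model = interaction_model(0.4)
    ds, truth = simulate_dataset(model, 400, 400, 20, seed=7)
    return ds, truth


def random_tables(rng, n, max_count=8, shape=(9, 2)):
    """Random small count tables for score-oracle comparisons."""
    return rng.integers(0, max_count + 1, size=(n, *shape))
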