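import numpy as np
import pytest
from hypothesis import settings

from fuzzygrn import ExpressionDataset

settings.register_profile("fuzzygrn", derandomize=True, deadline=None)
settings.load_profile("fuzzygrn")


def dataset_from_normalized(norm, gene_ids, phenotype=None):
    """Build a dataset whose normalized matrix equals *norm* (up to the
    arctan/tan round trip)."""
    norm = np.asarray(norm, dtype=float)
    log2 = np.tan(norm * np.pi / 2.0)
    times = 10.0 * np.arange(norm.shape[1])
    return ExpressionDataset(gene_ids=gene_ids, times=times, log2_matrix=log2,
                             phenotype=phenotype)


@pytest.fixture
def rng():
    return np.random.default_rng(20231114)


@pytest.fixture
def small_dataset(rng):
    """Four genes, 12 time points, generic continuous values."""
    norm = rng.uniform(-0.85, 0.85, size=(4, 12))
    return dataset_from_normalized(norm, ["gA", "gB", "gC", "gD"])
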