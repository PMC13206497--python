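import numpy as np
import pytest

from syncom_core import AbundanceTable, GeneratorConfig, SampleMeta, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic fermentation, shared across tests."""
    return generate_dataset(GeneratorConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_table(values, days=None, normalized=False, taxa=None):
    """Small abundance table helper for unit tests."""
    values = np.asarray(values, dtype=float)
    n_taxa, n_samples = values.shape
    taxa = taxa or [f"taxon_{i}" for i in range(n_taxa)]
    days = days if days is not None else list(range(n_samples))
    samples = [SampleMeta(f"s{j}", float(days[j]), 1) for j in range(n_samples)]
    return AbundanceTable(
        taxa=taxa, samples=samples, values=values, normalized=normalized
    )
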