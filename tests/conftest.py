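import numpy as np
import pytest

import tmelt


@pytest.fixture(scope="session")
def tiny_config() -> tmelt.SyntheticConfig:
    """Small hierarchical dataset: 5 species, strong within-species signal."""
    return tmelt.SyntheticConfig(
        n_species=5,
        proteins_per_species=60,
        embedding_dim=8,
        length_range=(8, 15),
        kappa=0.4,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config) -> tmelt.MeltomeDataset:
    return tmelt.generate_dataset(tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
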