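import pytest

from rhizostoich import SyntheticConfig, generate


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def synthetic_dataset(default_config):
    """One default balanced 3x5x3 dataset with its ground truth."""
    return generate(default_config, seed=11)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Zero-noise dataset: every downstream statistic is exactly recoverable."""
    cfg = SyntheticConfig(noise_cv={"soil": 0.0, "rhizo": 0.0,
                                    "enzyme": 0.0, "root": 0.0})
    return generate(cfg, seed=5)
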