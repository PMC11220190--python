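import numpy as np
import pytest

from mclseg.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    """A fast generator config used by I/O and pipeline tests."""
    return SyntheticConfig(
        height=32, width=32, n_bands=8, n_scenes=8, morphology="mix", seed=7
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config, tmp_path_factory):
    """8 scenes on disk: 3 labeled / 3 unlabeled / 2 test."""
    out = tmp_path_factory.mktemp("tiny_data")
    manifest = generate_dataset(tiny_config, out, labeled_fraction=0.5, test_count=2)
    return manifest
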