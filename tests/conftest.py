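import pytest

from gxetx.model import TwoFactorTranscriptomeModel
from gxetx.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=300, replicates_per_group=3, promoter_length=600, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    model = TwoFactorTranscriptomeModel(small_dataset.counts, small_dataset.design)
    return model.fit()
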