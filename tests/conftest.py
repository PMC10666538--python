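import numpy as np
import pytest
from hypothesis import settings

from pondcast.io_pretreat import assemble_intervals
from pondcast.synthetic import SynthConfig, generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_dataset():
    """Two ponds, 12 days, 3-day harvests: a fast end-to-end fixture."""
    cfg = SynthConfig(n_ponds=2, n_days=12, harvest_interval_days=(3,), seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_intervals(tiny_dataset):
    return assemble_intervals(tiny_dataset.densities(), tiny_dataset.sensor_series())


@pytest.fixture(scope="session")
def one_interval(tiny_intervals):
    return tiny_intervals[0]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
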