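import numpy as np
import pytest

from cequant import SynthConfig, generate, select_channels
from cequant.preprocess import RegionOfInterest, replace_roi, subtract_constant_baseline
from cequant.preprocess import detect_roi


def small_config(seed: int = 11, **kw) -> SynthConfig:
    """A compact experiment (fast to generate and align) for unit tests."""
    defaults = dict(
        seed=seed, sequence_length=30, lanes_per_batch=3,
        modifiers=("SHAPE", "DMS", "ddTTP"), n_samples=3600,
        mobility_start=500.0, mean_spacing=60.0, spacing_curvature=0.0,
        shift_range=60.0, scale_range=0.01,
    )
    defaults.update(kw)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_experiment():
    batchset, truth = generate(small_config())
    return batchset, truth


@pytest.fixture(scope="session")
def small_traces(small_experiment):
    batchset, truth = small_experiment
    ts = select_channels(batchset, 0, 1)
    ts = replace_roi(ts, detect_roi(ts))
    return subtract_constant_baseline(ts), truth


@pytest.fixture
def rng():
    return np.random.default_rng(202409)
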