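import warnings

import numpy as np
import pytest

from cisnet.pipeline import PipelineParams, run_all
from cisnet.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-geometry dataset shared by unit tests."""
    return generate_dataset(SyntheticConfig.small(seed=7))


@pytest.fixture(scope="session")
def default_dataset():
    """Default-scale dataset used by the end-to-end recovery tests."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    """Full pipeline run on the default dataset (coverage and TE stages are
    exercised separately on small inputs)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_all(
            default_dataset,
            PipelineParams(seed=11),
            run_coverage=False,
            run_te=False,
        )
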