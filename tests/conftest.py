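import numpy as np
import pytest

from bloodpool import (
    AnalysisConfig,
    PhantomConfig,
    SeedPoint,
    compute_all,
    generate_phantom,
)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.count_nonzero(a & b) / (np.count_nonzero(a) + np.count_nonzero(b))


@pytest.fixture(scope="session")
def sync_phantom():
    """Noise-free synchronous phantom at the default study conditions."""
    return generate_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def sync_params(sync_phantom):
    cine, truth = sync_phantom
    return compute_all(cine, SeedPoint(*truth.lv_center))


@pytest.fixture(scope="session")
def default_config():
    return AnalysisConfig()
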