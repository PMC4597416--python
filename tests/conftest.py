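import numpy as np
import pytest

from sbgg import OrdinalDataset, SamplerConfig
from sbgg.synthetic_data import generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_dataset():
    """Small planted-signal dataset shared across sampler tests."""
    return generate(n=120, p=12, k=3, n_signal=3, effect=2.0, seed=7)


@pytest.fixture
def tiny_config():
    """Short chain for smoke-level sampler runs."""
    return SamplerConfig(n_iter=300, burn_in=100, seed=3)


@pytest.fixture
def toy_dataset(rng):
    """Unstructured 3-category dataset for bookkeeping tests."""
    n, p, k = 40, 5, 3
    W = rng.standard_normal((n, p))
    y = np.tile(np.arange(1, k + 1), n // k + 1)[:n]
    return OrdinalDataset(
        W=W,
        y=y,
        sample_ids=[f"S{i}" for i in range(n)],
        feature_ids=[f"G{j}" for j in range(p)],
        k=k,
    )
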