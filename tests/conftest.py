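import numpy as np
import pytest

from rmkllpp.kernels import KernelSet
from rmkllpp.layers import OmicsLayer


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_layer(rng):
    """Complete 12-feature x 8-sample Gaussian layer."""
    values = rng.normal(size=(12, 8))
    return OmicsLayer(
        "toy",
        values,
        feature_ids=np.array([f"f{i}" for i in range(12)], dtype=object),
        sample_ids=np.array([f"S{i}" for i in range(8)], dtype=object),
    )


def random_kernel_set(rng, n=60, m=3, n_feats=(3, 10)) -> KernelSet:
    """Gaussian kernels of independent random feature blocks (strictly PD)."""
    kernels = []
    for _ in range(m):
        x = rng.normal(size=(n, rng.integers(*n_feats)))
        d2 = ((x[:, None] - x[None]) ** 2).sum(-1)
        kernels.append(np.exp(-d2 / (2 * np.median(d2))))
    return KernelSet(kernels, sample_ids=[f"S{i:03d}" for i in range(n)])
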