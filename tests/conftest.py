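import numpy as np
import pytest

from hegwas.ckks import CkksBackend, SchemeParams


@pytest.fixture
def make_backend():
    """Factory for small simulator backends (default 64 slots, full budget)."""

    def _make(log_ring_degree=7, **kwargs) -> CkksBackend:
        kwargs.setdefault("initial_budget_bits", 2440)
        noise_sigma = kwargs.pop("noise_sigma", 0.0)
        seed = kwargs.pop("seed", None)
        params = SchemeParams(log_ring_degree=log_ring_degree, **kwargs)
        return CkksBackend(params, noise_sigma=noise_sigma, seed=seed)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
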