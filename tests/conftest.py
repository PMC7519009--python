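import numpy as np
import pytest
from hypothesis import settings

from ideveg import Grid, KernelSpec, ModelParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def small_grid() -> Grid:
    """Coarse grid for unit tests (resolves sigma >= 0.3 kernels)."""
    return Grid(x_max=50.0, M=1024)


@pytest.fixture
def default_grid() -> Grid:
    return Grid()


@pytest.fixture
def season_params() -> ModelParams:
    """Season scaling at the classic demonstration point (A = 2B)."""
    return ModelParams.from_season_length(0.9, 0.45, T=0.1, d=500.0)


@pytest.fixture
def laplace_unit() -> KernelSpec:
    return KernelSpec("laplace", a=1.0)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
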