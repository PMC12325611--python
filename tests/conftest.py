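import numpy as np
import pytest

from dsbmotion import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def base_cfg():
    """Small, fast acquisition config used across tests."""
    return SimulationConfig(
        confinement_radius=0.8,
        diffusion_coeff=2e-3,
        n_frames=41,
        n_cells=5,
        drift_sd=0.05,
        seed=42,
    )


def uniform_ball(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """iid points uniform in a 3D ball — the confined track's stationary law."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)


def uniform_disk(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 2))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * radius * np.sqrt(rng.uniform(size=(n, 1)))
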