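import numpy as np
import pytest

from isocouple.synthgen import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def kappa_zero():
    z = np.zeros((3, 3))
    return {"AWAKE": z, "N1": z.copy(), "N2": z.copy()}


def one_way_kappa(src: int, dst: int, strength: float = 0.3):
    """Coupling matrices with a single directed link src -> dst (latent indices)."""
    K = np.zeros((3, 3))
    K[dst, src] = strength
    return {"AWAKE": K, "N1": K.copy(), "N2": K.copy()}


@pytest.fixture
def quiet_config():
    """Noise-free, uncoupled, jitter-free config: each latent a pure tone."""
    return SyntheticConfig(
        states=("AWAKE",),
        kappa=kappa_zero(),
        noise_sd=0.0,
        phase_noise_sd=0.0,
        freq_jitter=0.0,
        nuisance=(0.0, 0.0),
        grid_shape=(3, 3, 3),
        n_electrodes=4,
    )


@pytest.fixture
def small_config():
    """Small but noisy config for structural tests."""
    return SyntheticConfig(states=("AWAKE", "N2"), grid_shape=(4, 4, 4),
                           n_electrodes=4, seed=11)
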