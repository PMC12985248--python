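import numpy as np
import pytest

from hemodiff import BackboneConfig, SimConfig
from hemodiff.training import TranslationModel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clean_sim_config():
    """Noiseless regular rhythm at 60 BPM: every latent quantity trivial."""
    return SimConfig(
        heart_rate_bpm=60.0, rr_cv=0.0, rhythm="regular", ptt_s=0.25,
        fs=128.0, duration_s=10.0, noise_sd=0.0, baseline_wander_amp=0.0, seed=7,
    )


TINY_BACKBONE = dict(
    length=64, base_width=8, n_scales=3, attention_dim=8, groups=4,
    temb_dim=16, n_timesteps=50,
)


@pytest.fixture
def tiny_model():
    return TranslationModel(backbone_cfg=BackboneConfig(**TINY_BACKBONE), seed=3)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f(x)
        flat[i] = orig - eps
        lo = f(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g
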