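import numpy as np
import pytest

from strokekin.simulate import StrokeParams, make_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def zero_noise_params(**kw) -> StrokeParams:
    base = dict(
        seed=3, n_cycles=6, jitter_scale=0.0,
        gyro_noise_deg_s=1e-12, accel_noise_g=1e-12, mag_noise_gauss=1e-12,
        mount_misalignment_deg=0.0,
    )
    base.update(kw)
    return StrokeParams(**base)


@pytest.fixture(scope="session")
def small_bundle():
    """Noisy 8-cycle dataset shared by the mid-level tests."""
    return make_dataset(StrokeParams(seed=3, n_cycles=8))


@pytest.fixture(scope="session")
def clean_bundle():
    """Zero-noise, zero-jitter dataset for exact-recovery tests."""
    return make_dataset(zero_noise_params())
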