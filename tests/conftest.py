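import numpy as np
import pytest

import retphasor as rp
from retphasor.features import FeatureSpec, build_feature_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bands12():
    return rp.BandSet.default_msi()


@pytest.fixture
def bands3():
    return rp.BandSet((471.0, 595.0, 732.0), (20.0, 20.0, 20.0))


@pytest.fixture
def tiny_config():
    """Small, fast synthetic dataset configuration used across tests."""
    return rp.SyntheticConfig(n_healthy=6, n_diseased=6, image_size=(48, 48), seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest dataset generated once per session for feature-level tests."""
    cfg = rp.SyntheticConfig(n_healthy=10, n_diseased=10, image_size=(64, 64), seed=3)
    cases = rp.generate_cases(cfg)
    refs = rp.make_references(cfg)
    return cfg, cases, refs


def random_cube(rng, bands, H=5, W=4, lo=0.0, hi=1.0, stage="reflectance"):
    vals = rng.uniform(lo, hi, size=(H, W, bands.n))
    return rp.SpectralCube(vals, bands, stage=stage)
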