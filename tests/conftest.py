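import numpy as np
import pytest

from lfaquant import (
    DetectionConfig,
    PhantomConfig,
    RunConfig,
    analyze_strip,
    render_strip,
)


@pytest.fixture(scope="session")
def phantom_cfg():
    return PhantomConfig()


@pytest.fixture(scope="session")
def nf_cfg(phantom_cfg):
    """Noise-free, jitter-free default phantom."""
    return phantom_cfg.noise_free()


@pytest.fixture(scope="session")
def det_cfg():
    return DetectionConfig()


@pytest.fixture(scope="session")
def run_cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def analyze_noise_free(nf_cfg, det_cfg):
    """concentration -> StripMeasurement on a noise-free default phantom."""

    def fn(concentration, seed=0):
        img, _ = render_strip(concentration, nf_cfg, seed)
        return analyze_strip(img, nf_cfg.roi, det_cfg, keep_audit=False)

    return fn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
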