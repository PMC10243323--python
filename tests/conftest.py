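import numpy as np
import pytest

from brainmrqa.cine import SearchConfig, TrackingConfig
from brainmrqa.synth import PhantomSpec


@pytest.fixture(scope="session")
def head_spec():
    """Default-geometry head phantom, noiseless (160 px frames at 1.3 mm)."""
    return PhantomSpec(noise_sigma=0.0)


@pytest.fixture(scope="session")
def head_spec_noisy():
    """Default head phantom at brain SNR 30 (sigma 4 on brain 120)."""
    return PhantomSpec(noise_sigma=4.0)


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down head that fits a 64x64 frame at 1.3 mm spacing."""
    return PhantomSpec(
        skull_semiaxes_mm=(30.0, 36.0, 32.0),
        skull_thickness_mm=4.0,
        ventricle_semiaxes_mm=(4.0, 10.0, 6.0),
        ventricle_offset_mm=(7.0, -3.0, 0.0),
        noise_sigma=0.0,
        spacing_mm=1.3,
    )


@pytest.fixture(scope="session")
def center160():
    return (79.5, 79.5)


@pytest.fixture(scope="session")
def center64():
    return (31.5, 31.5)


@pytest.fixture(scope="session")
def fast_config():
    """Tracking config with a narrowed search for quick unit tests."""
    return TrackingConfig(search=SearchConfig(max_shift_mm=6.0, max_rot_deg=3.0,
                                              max_roi_points=2000))
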