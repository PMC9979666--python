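import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from opmdeskew import AcquisitionGeometry, RawSlice

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geom_small():
    """60 deg sheet, 0.5 um pixels, 1 um steps -> exactly 1 px shear/slice."""
    return AcquisitionGeometry(
        sheet_angle_deg=60.0,
        pixel_size_um=0.5,
        z_step_um=1.0,
        n_slices=5,
        raw_height_px=8,
        raw_width_px=8,
    )


def random_stack(rng, geom, high=1000):
    return [
        RawSlice(
            rng.integers(0, high, (geom.raw_height_px, geom.raw_width_px), dtype=np.uint16),
            k,
        )
        for k in range(geom.n_slices)
    ]


@pytest.fixture
def make_stack():
    return random_stack
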