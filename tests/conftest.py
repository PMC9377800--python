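import numpy as np
import pytest

from myoscale.orientation import OrientationField


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_field(angles, valid=None, grid_spacing=1.0, pixel_size=1.0):
    """Build an OrientationField directly from an angle grid."""
    angles = np.asarray(angles, dtype=float)
    if valid is None:
        valid = np.ones(angles.shape, dtype=bool)
    return OrientationField(
        angles=angles,
        grid_spacing=grid_spacing,
        origin_offset=0.0,
        pixel_size=pixel_size,
        valid_mask=np.asarray(valid, dtype=bool),
    )


def stripe_image(shape, angle_deg, wavelength=12.0):
    """Sinusoidal stripes whose ridges run along angle_deg (math convention,
    y up)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    ymath = -yy
    a = np.radians(angle_deg)
    gx, gy = -np.sin(a), np.cos(a)  # gradient normal to the stripes
    return np.cos(2 * np.pi / wavelength * (xx * gx + ymath * gy))
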