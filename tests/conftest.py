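import numpy as np
import pytest

from scrubshift import GridRaster, GridTransform
from scrubshift.raster import DEFAULT_HEIGHT_NODATA


@pytest.fixture
def unit_transform():
    """10×10 m extent: origin (0, 10), 1 m cells."""
    return GridTransform(0.0, 10.0, 1.0, 1.0)


@pytest.fixture
def fine_transform():
    """5 cm cells, the scale of a real survey."""
    return GridTransform(0.0, 5.0, 0.05, 0.05)


def make_height_raster(values, transform=None, nodata=DEFAULT_HEIGHT_NODATA,
                       crs="SYNTH:LOCAL"):
    values = np.asarray(values, dtype=np.float64)
    if transform is None:
        transform = GridTransform(0.0, values.shape[0] * 1.0, 1.0, 1.0)
    return GridRaster(values, transform, crs_tag=crs, nodata=nodata)


def make_mask(values, transform=None, nodata=255, crs="SYNTH:LOCAL"):
    values = np.asarray(values, dtype=np.int16)
    if transform is None:
        transform = GridTransform(0.0, values.shape[0] * 1.0, 1.0, 1.0)
    return GridRaster(values, transform, crs_tag=crs, nodata=nodata)


@pytest.fixture(scope="session")
def demo_sites():
    """Both preset demo scenes, generated once per session."""
    from scrubshift import generate_scene, preset_two_site_demo

    spec_a, spec_b = preset_two_site_demo()
    return {
        "A": (spec_a, *generate_scene(spec_a)),
        "B": (spec_b, *generate_scene(spec_b)),
    }
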