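import numpy as np
import pytest

from tofscape.grid import RasterGrid


@pytest.fixture
def grid_factory():
    """Build a small planar RasterGrid with 10 m pixels, origin top-left (0, H)."""

    def make(data, pixel_size=10.0, nodata=None):
        arr = np.asarray(data)
        return RasterGrid(
            data=arr,
            origin=(0.0, arr.shape[0] * pixel_size),
            pixel_size=pixel_size,
            nodata=nodata,
        )

    return make


@pytest.fixture(scope="session")
def default_scene():
    """One 256x256 synthetic scene with default (noisy) conditions."""
    from tofscape.synthetic import SceneParams, generate_landscape

    params = SceneParams(shape=(256, 256), seed=11)
    return params, generate_landscape(params)
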