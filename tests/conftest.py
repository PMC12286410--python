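import numpy as np
import pytest

from reefscale import ElevationRaster, SyntheticReefSpec, generate_reef_dem


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dem():
    """64x64 two-scale synthetic DEM with a 4-pixel nodata margin."""
    spec = SyntheticReefSpec(
        n_rows=64, n_cols=64, pixel_size=0.008, relief_wavelength=0.3,
        relief_amplitude=0.1, roughness_sd=0.01, nodata_margin=4, seed=7,
    )
    return generate_reef_dem(spec)


@pytest.fixture
def flat_raster():
    return ElevationRaster(
        values=np.full((8, 32), -5.0),
        nodata_mask=np.zeros((8, 32), dtype=bool),
        pixel_size=0.008,
    )


def make_raster(values, mask=None, pixel_size=0.008, **kw):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return ElevationRaster(values=values, nodata_mask=np.asarray(mask, bool),
                           pixel_size=pixel_size, **kw)
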