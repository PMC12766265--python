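import numpy as np
import pytest

from qdmsource import (
    Direction,
    DipoleSource,
    MomentVector,
    SensorGeometry,
    dipole_bz_map,
)


@pytest.fixture
def small_geom() -> SensorGeometry:
    """120 x 120 px at the instrument's 1.17 µm pixel size."""
    return SensorGeometry(pixel_size=1.17, n_cols=120, n_rows=120)


@pytest.fixture
def center_source(small_geom) -> DipoleSource:
    w = small_geom.n_cols * small_geom.pixel_size
    h = small_geom.n_rows * small_geom.pixel_size
    return DipoleSource(
        x=w / 2,
        y=h / 2,
        standoff=3.0,
        moment=MomentVector.from_direction(Direction(25.0, 15.0), 5e-16),
    )


def noisy_single_source_map(geom, src, noise_sigma, seed):
    """Forward map of one source plus i.i.d. Gaussian pixel noise."""
    rng = np.random.default_rng(seed)
    fmap = dipole_bz_map(src, geom)
    if noise_sigma > 0:
        fmap = fmap.copy_with(
            values=fmap.values + rng.normal(0.0, noise_sigma, fmap.values.shape)
        )
    return fmap
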