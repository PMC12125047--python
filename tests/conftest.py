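import numpy as np
import pytest

import lumiphantom as lp


@pytest.fixture(scope="session")
def beer_lambert_map():
    """Pure absorber, matched index, wide beam: analytic exp(-mua z)."""
    props = lp.OpticalProperties(mua=0.348, mus=0.0, g=0.0, n=1.0)
    grid = lp.GridSpec.for_beam(4.0, voxel_size=0.05, depth=3.0, width=6.0)
    beam = lp.BeamSpec(spot_diameter=4.0, irradiation_fluence=2.0)
    return lp.simulate_fluence(props, beam, grid, 500_000, seed=101)


@pytest.fixture(scope="session")
def phantom_map_small():
    """Characterized-phantom optics at reduced photon count (tests only)."""
    grid = lp.GridSpec.for_beam(2.0)
    beam = lp.BeamSpec(spot_diameter=2.0, irradiation_fluence=2.0)
    return lp.simulate_fluence(lp.PHANTOM_PROPERTIES, beam, grid, 200_000,
                               seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
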