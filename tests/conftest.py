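import numpy as np
import pytest

from cageflux import VesicleSpec


@pytest.fixture
def standard_vesicle() -> VesicleSpec:
    """200-nm vesicle under the standard shrinkage conditions:
    0.2 Osm/L sucrose inside, 0.4 Osm/L outside after 1:1 mixing."""
    return VesicleSpec(diameter_nm=200.0, c_in0_osm=0.2, c_out_osm=0.4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
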