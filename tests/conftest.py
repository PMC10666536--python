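import math

import pytest

from dibkit import osmotic as osm
from dibkit.synth import SynthConfig
from dibkit.types import MembraneComposition


@pytest.fixture
def config():
    """Default synthetic-study configuration."""
    return SynthConfig(seed=20230)


@pytest.fixture
def noiseless_config():
    """Study configuration with every noise source switched off."""
    return SynthConfig(seed=20230,
                       noise={"shrinkage": 0.0, "dsc": 0.0, "raman": 0.0})


@pytest.fixture
def popc():
    return MembraneComposition("POPC", "1:0", 0.0, 3)


def make_state(R=100.0, r=40.0, osm1=300.0, osm2=100.0):
    """Symmetric droplet pair with droplet 1 hypertonic."""
    V1, V2 = osm.volumes_from_radii(R, R, r, "sphere")
    return osm.DropletPairState(V1=V1, V2=V2, n1=osm1 * V1, n2=osm2 * V2,
                                A=math.pi * r * r)


@pytest.fixture
def droplet_state():
    return make_state()
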