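import pytest

from aortatear.geometry import (
    default_cohesive,
    default_layers,
    imaged_vessel_geometry,
    run_study,
)
from aortatear.inflation import VesselGeometry
from aortatear.recovery import recover_cylinder


@pytest.fixture(scope="session")
def layers():
    """Shipped (media, adventitia) parameter sets."""
    return default_layers()


@pytest.fixture(scope="session")
def cohesive():
    return default_cohesive()


@pytest.fixture(scope="session")
def vessel8(layers):
    """Zero-load two-layer cylinder with an 8 mm lumen radius."""
    media, adventitia = layers
    return VesselGeometry(8.0, (media, adventitia))


@pytest.fixture(scope="session")
def zero_load_s1_descending():
    """Recovered zero-load geometry of the Aorta-1 descending fixture."""
    vessel, _ = recover_cylinder(imaged_vessel_geometry(16.444), 80.0)
    return vessel


@pytest.fixture(scope="session")
def zero_load_s5_ascending():
    """Recovered zero-load geometry of the largest (ascending) fixture."""
    vessel, _ = recover_cylinder(imaged_vessel_geometry(41.381), 80.0)
    return vessel


@pytest.fixture(scope="session")
def default_sweep():
    """Full default study sweep (both orientations, all fixtures)."""
    return run_study()
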