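import numpy as np
import pytest

from druggability import CavitySpec, find_pockets, make_cavity_structure
from druggability.pockets import assign_shell


@pytest.fixture(scope="session")
def closed_polar_cavity():
    """Closed hollow-sphere structure with an all-polar lining, plus its pocket."""
    structure = make_cavity_structure(
        CavitySpec(inner_radius=6.0, mouth_aperture=0.0, lining_composition=0.0, seed=0)
    )
    pockets = find_pockets(structure)
    assert pockets, "construction guarantees one cavity"
    assign_shell(pockets[0], structure)
    return structure, pockets


@pytest.fixture(scope="session")
def small_cavity():
    """Cavity small enough that every enclosure ray chord is under the cutoff."""
    structure = make_cavity_structure(
        CavitySpec(inner_radius=3.5, shell_thickness=3.2, lining_composition=0.0, seed=1)
    )
    pockets = find_pockets(structure, min_volume=50.0)
    assert len(pockets) == 1
    assign_shell(pockets[0], structure)
    return structure, pockets[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
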