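import numpy as np
import pytest

from voxhazard.cube import MoleculeGeometry, VolumetricGrid
from voxhazard.synthetic import PaletteEntry, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def one_atom_geometry():
    return MoleculeGeometry((1,), (1.0,), np.zeros((1, 3)))


@pytest.fixture
def small_grid(rng):
    """A (4, 5, 6) grid with random values on an anisotropic cell."""
    return VolumetricGrid(
        origin=np.array([-1.0, 0.5, 2.0]),
        axes=np.diag([0.4, 0.5, 0.6]),
        values=rng.standard_normal((4, 5, 6)),
    )


@pytest.fixture
def tiny_synthetic_config():
    """Small, fast generator settings for unit tests (12^3 grid, 3-5 atoms)."""
    return SyntheticConfig(
        n_atoms_range=(3, 5),
        box_edge=12.0,
        grid_shape=(12, 12, 12),
        placement_margin=3.0,
        seed=7,
    )


@pytest.fixture
def two_element_palette():
    return (
        PaletteEntry(1, 1.0, 2.2),
        PaletteEntry(9, 1.0, 4.0),
    )
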