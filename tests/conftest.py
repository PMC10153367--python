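import numpy as np
import pytest

from mwaplan.bioheat import TissueProperties
from mwaplan.manufacturer import load_default_table
from mwaplan.source import SourceModel
from mwaplan.volumes import LabelVolume, VoxelGrid


@pytest.fixture(scope="session")
def props():
    return TissueProperties()


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def ref_model():
    """A realistic source model (near the table-calibrated optimum).

    Used by tests that need plausible ablation physics without paying for a
    full calibration; the calibration round trip itself is tested separately.
    """
    return SourceModel(axial_decay_mm=3.2, radial_decay_mm=2.5)


def make_sphere_mask(grid: VoxelGrid, center, radius_mm, role="ablation_pred") -> LabelVolume:
    x, y, z = grid.coordinate_arrays()
    r2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return LabelVolume(grid=grid, voxels=r2 <= radius_mm**2, role=role)


@pytest.fixture
def sphere_factory():
    return make_sphere_mask
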