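import numpy as np
import pytest

from quantev.geometry import CellSupport, ReferenceFrame
from quantev.synthetic import SyntheticCellSpec, make_cell_mask, center_frame


@pytest.fixture(scope="session")
def disk_cell() -> CellSupport:
    """Rasterized disk of radius 20 voxels, single plane."""
    return make_cell_mask(SyntheticCellSpec(shape="disk", size=20))


@pytest.fixture(scope="session")
def disk_frame(disk_cell) -> ReferenceFrame:
    return center_frame(disk_cell)


@pytest.fixture(scope="session")
def crossbow_cell() -> CellSupport:
    return make_cell_mask(SyntheticCellSpec(shape="crossbow", size=20))


def isotropic_events(center, n, rmax, seed, plane=0.0):
    """Events isotropic in angle, uniform over the disk of radius rmax."""
    rng = np.random.default_rng(seed)
    ang = rng.uniform(0, 2 * np.pi, n)
    rad = rmax * np.sqrt(rng.uniform(0, 1, n))
    return np.column_stack(
        [center[0] + rad * np.cos(ang), center[1] + rad * np.sin(ang), np.full(n, plane)]
    )
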