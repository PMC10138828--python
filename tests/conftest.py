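import numpy as np
import pytest

from ssmdscan.contact_maps import ContactCriterion, ContactMap
from ssmdscan.kernels import build_kernel_library
from ssmdscan.traj_io import SystemFrame


@pytest.fixture(scope="session")
def lib8():
    return build_kernel_library(8)


@pytest.fixture(scope="session")
def lib4():
    return build_kernel_library(4)


def two_molecule_map(block: np.ndarray) -> ContactMap:
    """Contact map of a two-molecule system whose (0,1) block is given."""
    res = block.shape[0]
    C = np.zeros((2 * res, 2 * res), dtype=np.uint8)
    C[:res, res:] = block
    C[res:, :res] = block.T
    return ContactMap(
        C=C,
        criterion=ContactCriterion.beta(),
        index_offsets=np.array([0, res, 2 * res]),
        molecule_lengths=(res, res),
    )


def frame_from_points(*molecules) -> SystemFrame:
    return SystemFrame(
        frame_index=0,
        coordinates=tuple(np.asarray(m, dtype=float) for m in molecules),
    )
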