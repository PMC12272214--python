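import numpy as np
import pytest

import lumbobold as lb
from lumbobold import design


@pytest.fixture(scope="session")
def geom():
    """Default 48x48x15 phantom geometry."""
    return lb.build_geometry()


@pytest.fixture(scope="session")
def small_geom():
    """Reduced grid for pipeline-level tests."""
    return lb.build_geometry(
        lb.GeometryConfig(grid_shape=(32, 32, 10), center=(16.0, 16.0),
                          lse_slice_index=6, tip_slice_index=1)
    )


@pytest.fixture(scope="session")
def paradigm40():
    return design.make_block_paradigm(15.0, 40)


@pytest.fixture(scope="session")
def paradigm10():
    """Short 10-block paradigm (150 s) for pipeline tests."""
    return design.make_block_paradigm(15.0, 10)


@pytest.fixture(scope="session")
def paradigm20():
    """Half-length 20-block paradigm (300 s): enough task cycles for
    stable run-level variance estimation at desk scale."""
    return design.make_block_paradigm(15.0, 20)


@pytest.fixture(scope="session")
def hrf_basis():
    return design.make_hrf_basis()
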