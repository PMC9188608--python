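import numpy as np
import pytest

from microct_qc.volumes_io import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(20260)


@pytest.fixture
def constant_volume():
    """A 5-slice constant grid at water-like grey, 0.5 mm spacing."""
    return Volume(
        voxels=np.full((5, 40, 40), 2000.0),
        spacing=(0.5, 0.5, 0.5),
    )


@pytest.fixture
def integer_volume(rng):
    """A small random-integer grid for round-trip tests."""
    return Volume(
        voxels=rng.integers(0, 4096, size=(6, 32, 32)).astype(np.uint16),
        spacing=(0.05, 0.05, 0.05),
        origin=(0.0, -0.775, -0.775),
    )
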