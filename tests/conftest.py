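import numpy as np
import pytest

from pesmap.geom import Geometry
from pesmap.potentials import LennardJones


@pytest.fixture
def lj():
    return LennardJones()


@pytest.fixture
def water():
    # bent triatomic with realistic O–H bonds
    return Geometry(
        ["O", "H", "H"],
        [[0.0, 0.0, 0.117], [0.0, 0.757, -0.467], [0.0, -0.757, -0.467]],
        label="water",
    )
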