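import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from msiflnp import AssociationMatrix, MsifLnpParams, PlantedBlockSpec, generate


@pytest.fixture
def tiny_assoc() -> AssociationMatrix:
    """2x2 association with one shared disease."""
    return AssociationMatrix(
        np.array([[1.0, 1.0], [1.0, 0.0]]), ["m1", "m2"], ["d1", "d2"]
    )


@pytest.fixture
def small_assoc() -> AssociationMatrix:
    """6x4 association with two clear microbe groups and one isolated microbe."""
    values = np.array(
        [
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [1, 0, 0, 0],
            [0, 0, 1, 1],
            [0, 0, 1, 1],
            [0, 0, 0, 0],
        ],
        dtype=float,
    )
    return AssociationMatrix(
        values, [f"m{i}" for i in range(6)], [f"d{j}" for j in range(4)]
    )


@pytest.fixture(scope="session")
def planted():
    """Planted-block dataset at generator defaults, seed 7."""
    return generate(PlantedBlockSpec(seed=7))


@pytest.fixture
def synthetic_params() -> MsifLnpParams:
    """Defaults with the disease neighbor count scaled to the generator's nd=20."""
    return MsifLnpParams(n_neighbors_disease=13)
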