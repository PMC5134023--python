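import numpy as np
import pytest

from epitrack import GenerationConfig, generate_tissue, hexagonal_mesh


@pytest.fixture(scope="session")
def hex5() -> "Mesh":
    """5x5 regular hexagonal lattice."""
    return hexagonal_mesh(5, 5)


@pytest.fixture(scope="session")
def tissue9() -> "Mesh":
    """A fixed 9x9 Voronoi/Lloyd tissue."""
    return generate_tissue(GenerationConfig(m=9, n=9, rng_seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
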