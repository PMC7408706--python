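import numpy as np
import pytest

from scanbody_congruence import ScanbodySpec, SurfaceIndex
from scanbody_congruence.synthetic_scanbody import build_library_mesh


@pytest.fixture(scope="session")
def spec() -> ScanbodySpec:
    """Default scanbody geometry used across the suite."""
    return ScanbodySpec()


@pytest.fixture(scope="session")
def library(spec):
    return build_library_mesh(spec)


@pytest.fixture(scope="session")
def library_index(library):
    return SurfaceIndex(library)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
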