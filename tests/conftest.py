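import numpy as np
import pytest

from screenerr import make_mock_shrna_library, make_orf_bc_library


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def eleven_lib():
    """Equimolar 11-clone sublibrary, one barcode per ORF (the assay shape)."""
    return make_orf_bc_library(11, 1, 30, "5BC", rng=np.random.default_rng(11))


@pytest.fixture(scope="session")
def mock_lib():
    """The 1000-hairpin mock library in five exact GC strata."""
    return make_mock_shrna_library(np.random.default_rng(7))
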