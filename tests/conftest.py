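import numpy as np
import pytest

from cladecoev import CladeMap, ProfileMatrix


@pytest.fixture
def toy_matrix() -> ProfileMatrix:
    """3 genes x 4 species LNPP matrix with simple values."""
    values = np.array(
        [
            [1.0, 0.5, 0.2, 0.0],
            [0.9, 0.4, 0.0, 0.1],
            [0.8, 0.8, 0.8, 0.8],
        ]
    )
    return ProfileMatrix(["ALAD", "FECH", "HMBS"], ["sp1", "sp2", "sp3", "sp4"], values)


@pytest.fixture
def toy_clades() -> CladeMap:
    return CladeMap(
        {
            "sp1": {"Vertebrata"},
            "sp2": {"Vertebrata"},
            "sp3": {"Fungi"},
            "sp4": {"Fungi"},
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
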