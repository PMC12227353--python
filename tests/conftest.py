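import numpy as np
import pytest

from connocorr.synthetic import AtlasSpec, make_atlas


@pytest.fixture(scope="session")
def atlas114():
    return make_atlas()


@pytest.fixture(scope="session")
def atlas_small():
    """Tiny atlas: 2 networks x 2 ROIs per hemisphere + 1 subcortical pair
    (10 ROIs) — small enough for Monte-Carlo convergence bounds."""
    return make_atlas(4, ("NetA", "NetB"), ("Thalamus",))


@pytest.fixture(scope="session")
def atlas4():
    """4 ROIs, 2 networks, no homotopic pairs: hand-checkable covariance."""
    return AtlasSpec(("r1", "r2", "r3", "r4"), ("A", "A", "B", "B"), ())


@pytest.fixture()
def rng():
    return np.random.default_rng(20250929)
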