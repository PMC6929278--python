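import numpy as np
import pytest

from hexablock.residue_profiles import NormalizedPSSM
from hexablock.synthetic_fixtures import (
    FixtureSpec,
    make_decoy_ladder,
    make_synthetic_profile,
    make_toy_complex,
)


@pytest.fixture(scope="session")
def toy_complex():
    """Two 30-residue ideal helices with a ~4 A closest approach."""
    return make_toy_complex(FixtureSpec(chain_lengths=(30, 30), contact_distance=4.0, seed=1))


@pytest.fixture(scope="session")
def toy_profiles(toy_complex):
    return {
        "A": make_synthetic_profile(30, seed=11)[1],
        "B": make_synthetic_profile(30, seed=12)[1],
    }


@pytest.fixture(scope="session")
def small_ladder(toy_complex):
    """5 magnitudes x 6 decoys with true CAPRI labels."""
    return make_decoy_ladder(toy_complex, n_per_magnitude=6, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def constant_profile():
    """Degenerate-free constant-signal profile: all rows identical."""
    row = np.linspace(0.0, 1.0, 20)
    return NormalizedPSSM(np.tile(row, (30, 1)))
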