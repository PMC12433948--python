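import numpy as np
import pytest

from caprune.fixtures import make_random_fixture
from caprune.structure_io import parse_structure


def contact_keys(contacts):
    return {c.key() for c in contacts}


def random_battery(tmp_dir, n_fixtures, seed0=0, max_residues=50):
    """Deterministic battery of parsed random-walk fixtures of 2..max
    residues."""
    rng = np.random.default_rng(12345 + seed0)
    proteins = []
    for seed in range(seed0, seed0 + n_fixtures):
        n = int(rng.integers(2, max_residues + 1))
        path = make_random_fixture(n, seed, tmp_dir)
        proteins.append(parse_structure(path))
    return proteins


@pytest.fixture(scope="session")
def small_battery(tmp_path_factory):
    """15 parsed random fixtures shared by the equivalence unit tests."""
    return random_battery(tmp_path_factory.mktemp("battery"), 15)
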