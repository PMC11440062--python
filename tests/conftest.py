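import numpy as np
import pytest

from phosmap import FixtureConfig, PlantedMotif, generate_fixture
from phosmap._alphabet import AA20


def random_windows(rng, n, width=15, center="S"):
    """Uniform random windows with a fixed central residue."""
    half = width // 2
    wins = []
    for _ in range(n):
        chars = rng.choice(list(AA20), width)
        chars[half] = center
        wins.append("".join(chars))
    return wins


@pytest.fixture(scope="session")
def small_bundle():
    """A small deterministic fixture bundle shared across module tests."""
    config = FixtureConfig(
        seed=42,
        n_proteins=8,
        n_sites=60,
        n_differential=8,
        planted_motifs=(PlantedMotif(constraints=((-3, "R"),), fraction=0.3),),
    )
    return generate_fixture(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
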