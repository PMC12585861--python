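import numpy as np
import pytest

from spiralshape.io_formats import LandmarkConfiguration, Phylogeny
from spiralshape.synthetic import SpiralParams, generate_cochlea, generate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def star_tree():
    """Four tips hanging directly off the root, unit branches."""
    labels = [None] + [f"t{i + 1}" for i in range(4)]
    return Phylogeny([-1, 0, 0, 0, 0], [0, 1, 1, 1, 1], labels)


@pytest.fixture
def three_taxon_tree():
    """((B:0.5,C:0.5):0.5,A:1); depths all 1."""
    return Phylogeny(
        [-1, 0, 0, 2, 2], [0.0, 1.0, 0.5, 0.5, 0.5],
        [None, "A", None, "B", "C"],
    )


@pytest.fixture
def cochlea():
    """A clean 2.5-turn conical helico-spiral."""
    return generate_cochlea(
        SpiralParams(n_turns=2.5, taper=0.1, pitch=0.08, n_points=200, seed=1)
    )


@pytest.fixture
def small_tree():
    return generate_tree(16, seed=3)


def random_config(rng, k=12, specimen="s", species="sp"):
    return LandmarkConfiguration(
        specimen_id=specimen, species_id=species, side="right",
        points=rng.normal(size=(k, 3)),
    )
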