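import pytest

from phycomp.simulate import gen_species_tree, tf_fixture
from phycomp.simulate.traits import tf_fixture_tree


@pytest.fixture(scope="session")
def backbone_tree():
    return gen_species_tree()


@pytest.fixture(scope="session")
def tf_matrix():
    return tf_fixture()


@pytest.fixture(scope="session")
def tf_tree():
    return tf_fixture_tree()


@pytest.fixture(scope="session")
def fig2a_partition_spec():
    """Printed Venn partition over the three Viridiplantae lineages,
    plus group-unique cells."""
    P, C, S = "Prasinodermophyta", "Chlorophyta", "Streptophyta"
    return {
        frozenset({P, C, S}): 3292,
        frozenset({P, C}): 621,
        frozenset({P, S}): 179,
        frozenset({C, S}): 760,
        frozenset({P}): 1356,
        frozenset({C}): 500,
        frozenset({S}): 400,
    }


@pytest.fixture(scope="session")
def viridiplantae_groups():
    return {
        "Prasinodermophyta": ["P. coloniale"],
        "Chlorophyta": ["M. commoda"],
        "Streptophyta": ["C. atmophyticus"],
    }
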