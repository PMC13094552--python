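import numpy as np
import pytest

from suctionmorph.data_io import Character, CharacterMatrix, LabelTable, suction_characters
from suctionmorph.phylo import parse_newick
from suctionmorph.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def three_tip_tree():
    """((A:1,B:1):1,C:2); V = [[2,1,0],[1,2,0],[0,0,2]]."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def six_tip_tree():
    """Fixture tree used for the frozen GLS/phylosig oracle values."""
    return parse_newick(
        "(((A:1.5,B:1.5):1.0,(C:0.8,D:0.8):1.7):0.5,(E:2.0,F:2.0):1.0);")


@pytest.fixture(scope="session")
def six_tip_values():
    return {"A": 1.2, "B": 0.9, "C": 2.5, "D": 2.8, "E": 0.3, "F": 0.1}


@pytest.fixture(scope="session")
def six_tip_labels():
    return LabelTable({
        "A": "Suction", "B": "Other", "C": "Suction",
        "D": "Suction", "E": "Other", "F": "Other",
    })


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic study at default (study-condition) settings."""
    return generate_dataset(SynthConfig(seed=11))


@pytest.fixture
def tiny_matrix():
    chars = [Character("c1"), Character("c2", "soft_tissue")]
    return CharacterMatrix(["Tax_a", "Tax b"], chars,
                           np.array([[0.0, 3.0], [1.0, 2.0]]))
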