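import numpy as np
import pytest

from kinlearn.family import FamilyTree, Person, build_demo_tree
from kinlearn.grammar import base_grammar
from kinlearn.lexicon import ground_truth
from kinlearn.observation import LikelihoodDomain, ObservationConfig


@pytest.fixture(scope="session")
def demo_tree():
    return build_demo_tree()


@pytest.fixture(scope="session")
def grammar(demo_tree):
    return base_grammar(demo_tree)


@pytest.fixture(scope="session")
def english():
    return ground_truth("english")


@pytest.fixture(scope="session")
def all_lexicons():
    return {lang: ground_truth(lang) for lang in
            ("pukapuka", "english", "turkish", "yanomamo")}


@pytest.fixture(scope="session")
def obs():
    return ObservationConfig(alpha=0.9, seed=0)


@pytest.fixture(scope="session")
def dom(demo_tree):
    return LikelihoodDomain.for_tree(demo_tree, n_words=9)


@pytest.fixture()
def tiny_tree():
    """Ego + sibling + parents; ranks 1..4; a minimal 2-generation context."""
    persons = [
        Person("ego", "Ego", "female", 0, "h1", 1),
        Person("bro", "Bro", "male", 0, "h1", 2),
        Person("mom", "Mom", "female", 1, "h1", 3),
        Person("dad", "Dad", "male", 1, "h1", 4),
    ]
    return FamilyTree(
        persons=persons,
        parent_edges=[("mom", "ego"), ("dad", "ego"), ("mom", "bro"), ("dad", "bro")],
        lateral_edges=[("dad", "mom")],
        speakers=["ego", "bro", "mom", "dad"],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
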