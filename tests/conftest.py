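import pytest

from crossgsa.core import AnnotationCorpus, GeneID, GeneSet


def gid(token, species="human"):
    return GeneID(species, str(token))


def gset(name, tokens, species="human", category="private/test"):
    return GeneSet(
        name, species, category, frozenset(gid(t, species) for t in tokens)
    )


@pytest.fixture
def small_corpus():
    """10-gene universe with three phenotype sets, one of them tiny."""
    corpus = AnnotationCorpus()
    inventory = [gid(i) for i in range(1, 11)]
    corpus.set_inventory("human", inventory)
    corpus.add_set(gset("term_a", [1, 2, 3, 4], category="public/phenotype"))
    corpus.add_set(gset("term_b", [3, 4, 5, 6, 7], category="public/phenotype"))
    corpus.add_set(gset("term_c", [8, 9], category="public/phenotype"))
    return corpus


@pytest.fixture(scope="session")
def survey():
    """The reconstructed seven-species coverage survey (built once)."""
    from crossgsa.survey import build_survey

    return build_survey()
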