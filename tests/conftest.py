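import pytest

from relmine.lexicon import InteractionLexicon
from relmine.synthetic import GeneratorParams, generate_corpus, worked_examples


@pytest.fixture(scope="session")
def erbb_sentence():
    """Neuregulin/ErbB sentence with transcribed dependency tree."""
    return worked_examples()[0]


@pytest.fixture(scope="session")
def p53_sentence():
    """Long p53/TAF sentence whose dependency path exceeds the RD bound."""
    return worked_examples()[1]


@pytest.fixture(scope="session")
def induce_lexicon_fixture():
    return InteractionLexicon(verbs={"induce"})


@pytest.fixture(scope="session")
def interact_lexicon_fixture():
    return InteractionLexicon(verbs={"interact"})


@pytest.fixture(scope="session")
def small_corpus():
    """A 60-sentence synthetic corpus with parses and gold."""
    return generate_corpus(GeneratorParams(n_sentences=60, seed=7))
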