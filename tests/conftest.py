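import pytest

from tisk import (
    FixtureRecipe,
    Lexicon,
    ParameterSet,
    PhonemeInventory,
    Word,
    generate,
)

# the classic 14-phoneme inventory used by small interactive-activation models
TRACE14 = ("p", "b", "t", "d", "k", "g", "s", "S", "r", "l", "a", "i", "u", "^")


@pytest.fixture
def anadrome_lexicon():
    """Two words with the same phonemes in opposite order."""
    inv = PhonemeInventory(("d", "a", "g"))
    lex = Lexicon(
        [Word("dag", ("d", "a", "g")), Word("gad", ("g", "a", "d"))], inv
    )
    return inv, lex


@pytest.fixture
def competitor_lexicon():
    """A target with one same-length cohort, one strict rhyme, and unrelated
    baseline words — the planted-class fixture for competitor curves."""
    inv = PhonemeInventory(tuple("bikerltdagsunmo"))
    words = [
        Word("target", ("b", "i", "k", "e", "r")),
        Word("cohort", ("b", "i", "t", "l", "d")),
        Word("rhyme", ("l", "i", "k", "e", "r")),
        Word("base1", ("d", "a", "g")),
        Word("base2", ("t", "u", "d")),
        Word("base3", ("s", "u", "n")),
        Word("base4", ("m", "o", "d")),
    ]
    return inv, Lexicon(words, inv)


@pytest.fixture
def embedding_lexicon():
    """A short word plus the same word extended by one phoneme (onset-embedded
    cohort pair), with unrelated fillers."""
    inv = PhonemeInventory(tuple("trihdamezok"))
    words = [
        Word("trit", tuple("trit")),
        Word("triti", tuple("triti")),
        Word("dam", tuple("dam")),
        Word("zok", tuple("zok")),
    ]
    return inv, Lexicon(words, inv)


@pytest.fixture
def random_fixture():
    """Generated lexicon with one planted structure of every kind."""
    return generate(FixtureRecipe(seed=7, inventory_size=10, n_words=30))


@pytest.fixture
def params():
    return ParameterSet()
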