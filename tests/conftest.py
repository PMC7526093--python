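import pytest

from subtag import (
    AnnotatedDocument,
    EntitySpan,
    GeneratorConfig,
    SubwordToken,
    SubwordVocab,
    build_vocab,
    generate_corpus,
)

TEST_DICT_SIZES = {"DZ": 50, "SX": 20, "BP": 20}


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(dict_sizes=dict(TEST_DICT_SIZES), attach_prob=0.4, seed=7)


@pytest.fixture(scope="session")
def small_corpus(gen_config):
    return generate_corpus(gen_config, 120)


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    return build_vocab(small_corpus)


@pytest.fixture
def toy_vocab():
    # the worked micro-fixture used across modules: "abcde fg" with the
    # entity "abcd" whose tail "e" is a glued non-entity continuation
    return SubwordVocab.from_tokens(["ab", "##cd", "##e", "fg", "play", "##ing"])


@pytest.fixture
def toy_doc():
    return AnnotatedDocument("toy-0", "abcde fg", (EntitySpan(0, 4, "BP"),))


@pytest.fixture
def toy_tokens():
    return [
        SubwordToken("ab", 0, 2),
        SubwordToken("##cd", 2, 4),
        SubwordToken("##e", 4, 5),
        SubwordToken("fg", 6, 8),
    ]
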