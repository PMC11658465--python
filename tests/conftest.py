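import numpy as np
import pytest

from jtis import (
    EncoderConfig,
    LabelSchema,
    build_constraint_map,
    build_samples,
    build_vocab,
    read_pubtator,
)
from jtis.synthetic import (
    BIORED_ENTITY_TYPES,
    BIORED_RELATION_TYPES,
    SynthConfig,
    generate_corpus,
)

TOY_BLOCK = """\
1|t|A.
1|a|B binds C.
1\t3\t4\tB\tGene\tG1
1\t11\t12\tC\tChemical\tC1
1\tBind\tG1\tC1\tNovel
"""


@pytest.fixture
def toy_doc():
    return read_pubtator(TOY_BLOCK)[0]


@pytest.fixture(scope="session")
def small_corpus():
    """A 12-document synthetic corpus with coreference and relations."""
    return generate_corpus(SynthConfig(n_docs=12, seed=7))


@pytest.fixture(scope="session")
def small_setup(small_corpus):
    """(docs, schema, encoder_config, samples) over the small corpus."""
    schema = LabelSchema(
        BIORED_ENTITY_TYPES, BIORED_RELATION_TYPES, build_constraint_map(small_corpus)
    )
    enc = EncoderConfig(vocab=build_vocab(small_corpus), max_length=128)
    samples = [s for d in small_corpus for s in build_samples(d, schema, enc)]
    return small_corpus, schema, enc, samples
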