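import pytest

from coreflink.corpus import (
    AnnotationLayer,
    CoreferenceLink,
    Document,
    EventTrigger,
    RoleLink,
    Token,
)
from coreflink.synth import SyntheticConfig, generate


def _tok(i, s, word, pos, ne, chunk, head, dep):
    return Token(i, s, word, word.lower(), pos, ne, chunk, head, dep)


@pytest.fixture
def fig_doc() -> Document:
    """Two-sentence worked example: an anaphoric "The region" in S2 whose
    antecedent "The IRF-2 promoter region" heads S1, giving one intra Theme
    (13->11), one Cause (13->15), and a cross-sentence Theme (13->4) that
    only exists because of corefer(11, 4)."""
    tokens = [
        # S1: Previously The IRF-2 promoter region was studied in cells .
        _tok(0, 0, "Previously", "RB", "O", "O", 6, "advmod"),
        _tok(1, 0, "The", "DT", "O", "B-NP", 4, "det"),
        _tok(2, 0, "IRF-2", "NN", "PROTEIN", "I-NP", 4, "nmod"),
        _tok(3, 0, "promoter", "NN", "O", "I-NP", 4, "compound"),
        _tok(4, 0, "region", "NN", "DNA", "I-NP", 6, "nsubj"),
        _tok(5, 0, "was", "VBD", "O", "O", 6, "aux"),
        _tok(6, 0, "studied", "VBN", "O", "O", None, "ROOT"),
        _tok(7, 0, "in", "IN", "O", "O", 6, "prep"),
        _tok(8, 0, "cells", "NNS", "O", "O", 7, "pobj"),
        _tok(9, 0, ".", ".", "O", "O", 6, "punct"),
        # S2: The region is inducible both interferons .
        _tok(10, 1, "The", "DT", "O", "B-NP", 11, "det"),
        _tok(11, 1, "region", "NN", "DNA", "I-NP", 13, "nsubj"),
        _tok(12, 1, "is", "VBZ", "O", "O", 13, "cop"),
        _tok(13, 1, "inducible", "JJ", "O", "O", None, "ROOT"),
        _tok(14, 1, "both", "DT", "O", "B-NP", 15, "det"),
        _tok(15, 1, "interferons", "NNS", "PROTEIN", "I-NP", 13, "nmod"),
        _tok(16, 1, ".", ".", "O", "O", 13, "punct"),
    ]
    gold = AnnotationLayer(
        triggers=[EventTrigger(13, "Regulation")],
        roles=[
            RoleLink(13, 11, "Theme"),
            RoleLink(13, 15, "Cause"),
            RoleLink(13, 4, "Theme"),
        ],
        corefs=[CoreferenceLink(11, 4)],
    )
    doc = Document("fig1", tokens, gold=gold)
    doc.validate()
    return doc


@pytest.fixture(scope="session")
def small_corpus() -> list[Document]:
    return generate(SyntheticConfig(n_docs=25, seed=7))


@pytest.fixture(scope="session")
def train_corpus() -> list[Document]:
    return generate(SyntheticConfig(n_docs=60, seed=41))


@pytest.fixture(scope="session")
def test_corpus() -> list[Document]:
    return generate(SyntheticConfig(n_docs=20, seed=42))
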