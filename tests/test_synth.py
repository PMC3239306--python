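import dataclasses

import pytest

from coreflink.annotation_io import document_to_obj
from coreflink.corpus import LinkCategory, categorize_link, coref_closure
from coreflink.pipeline import propagate_transitivity
from coreflink.synth import (
    ConfigError,
    SyntheticConfig,
    corrupt_coref,
    generate,
    mention_pair_pool,
)


def test_generation_is_deterministic():
    a = generate(SyntheticConfig(n_docs=5, seed=99))
    b = generate(SyntheticConfig(n_docs=5, seed=99))
    assert [document_to_obj(d) for d in a] == [document_to_obj(d) for d in b]


def test_different_seeds_differ():
    a = generate(SyntheticConfig(n_docs=5, seed=1))
    b = generate(SyntheticConfig(n_docs=5, seed=2))
    assert [document_to_obj(d) for d in a] != [document_to_obj(d) for d in b]


def test_documents_are_valid(small_corpus):
    for doc in small_corpus:
        doc.validate()


def test_every_event_has_a_theme(small_corpus):
    for doc in small_corpus:
        themed = {r.event_anchor for r in doc.gold.roles if r.role == "Theme"}
        for trig in doc.gold.triggers:
            assert trig.anchor in themed


def test_gold_roles_are_closed_under_transitivity(small_corpus):
    for doc in small_corpus:
        clusters = coref_closure(doc.gold.corefs)
        closed = propagate_transitivity(doc.gold.roles, clusters)
        assert set(doc.gold.roles) == closed


def test_corpus_contains_all_link_categories(small_corpus):
    seen = set()
    for doc in small_corpus:
        clusters = coref_closure(doc.gold.corefs)
        for link in doc.gold.roles:
            seen.add(categorize_link(link, clusters, doc))
    assert seen == {LinkCategory.CROSS, LinkCategory.W_ANT, LinkCategory.NORMAL}


def test_corpus_contains_non_argument_chains(small_corpus):
    # some coreferent mentions must carry no role at all — coreference is
    # not, by itself, evidence of argument-hood
    found = False
    for doc in small_corpus:
        args = {r.arg_anchor for r in doc.gold.roles}
        clustered = {m for c in doc.gold.corefs for m in (c.anaphor, c.antecedent)}
        if clustered - args:
            found = True
    assert found


def test_zero_anaphora_links_have_no_chain():
    cfg = SyntheticConfig(
        n_docs=40, coref_chain_rate=0.0, distractor_chain_rate=0.0,
        cross_link_rate=0.5, zero_anaphora_fraction=1.0, seed=4,
    )
    docs = generate(cfg)
    crossed = 0
    for doc in docs:
        assert doc.gold.corefs == []
        for link in doc.gold.roles:
            if doc.sentence_of(link.event_anchor) != doc.sentence_of(link.arg_anchor):
                crossed += 1
    assert crossed > 0


def test_config_rejects_out_of_range_rates():
    with pytest.raises(ConfigError):
        SyntheticConfig(trigger_rate=1.5).validate()
    with pytest.raises(ConfigError):
        SyntheticConfig(zero_anaphora_fraction=-0.1).validate()


def test_config_rejects_unreachable_cross_links():
    cfg = SyntheticConfig(
        cross_link_rate=0.3, coref_chain_rate=0.0, zero_anaphora_fraction=0.2
    )
    with pytest.raises(ConfigError):
        cfg.validate()


def test_config_rejects_unknown_event_type():
    with pytest.raises(ConfigError):
        SyntheticConfig(event_types=("Phosphorylation",)).validate()


# -- coreference degradation --------------------------------------------------


def test_corrupt_coref_full_recall_full_precision(small_corpus):
    doc = max(small_corpus, key=lambda d: len(d.gold.corefs))
    pool = mention_pair_pool(doc)
    out = corrupt_coref(doc.gold.corefs, pool, precision=1.0, recall=1.0, seed=0)
    assert out == sorted(doc.gold.corefs)


def test_corrupt_coref_injects_spurious_links(small_corpus):
    doc = max(small_corpus, key=lambda d: len(d.gold.corefs))
    pool = mention_pair_pool(doc)
    out = corrupt_coref(doc.gold.corefs, pool, precision=0.5, recall=1.0, seed=0)
    kept = set(doc.gold.corefs)
    assert kept <= set(out)
    assert len(out) == 2 * len(kept)


def test_corrupt_coref_rejects_bad_targets(small_corpus):
    doc = small_corpus[0]
    with pytest.raises(ConfigError):
        corrupt_coref(doc.gold.corefs, [], precision=0.0, recall=1.0, seed=0)
    with pytest.raises(ConfigError):
        corrupt_coref(doc.gold.corefs, [], precision=1.0, recall=2.0, seed=0)
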