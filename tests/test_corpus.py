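import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coreflink.corpus import (
    AnnotationLayer,
    CoreferenceLink,
    CorpusError,
    Document,
    EntityClusters,
    EventTrigger,
    LinkCategory,
    RoleLink,
    Token,
    anchor_token,
    candidate_arguments,
    categorize_link,
    coref_closure,
)


def _tok(i, s, head, dep="dep", word="w", pos="NN"):
    return Token(i, s, word, word.lower(), pos, "O", "O", head, dep)


# -- annotation invariants ---------------------------------------------------


def test_role_link_rejects_self_link():
    with pytest.raises(CorpusError):
        RoleLink(3, 3, "Theme")


def test_role_link_rejects_unknown_role():
    with pytest.raises(CorpusError):
        RoleLink(1, 2, "Agent")


def test_coreference_link_requires_antecedent_before_anaphor():
    with pytest.raises(CorpusError):
        CoreferenceLink(2, 5)
    link = CoreferenceLink(5, 2)
    assert (link.anaphor, link.antecedent) == (5, 2)


def test_document_validate_accepts_wellformed(fig_doc):
    fig_doc.validate()  # should not raise


def test_document_validate_rejects_two_roots():
    tokens = [_tok(0, 0, None, "ROOT"), _tok(1, 0, None, "ROOT")]
    with pytest.raises(CorpusError):
        Document("d", tokens).validate()


def test_document_validate_rejects_cross_sentence_head():
    tokens = [_tok(0, 0, None, "ROOT"), _tok(1, 1, 0)]
    with pytest.raises(CorpusError):
        Document("d", tokens).validate()


def test_document_validate_rejects_out_of_range_anchor():
    tokens = [_tok(0, 0, None, "ROOT")]
    doc = Document("d", tokens, gold=AnnotationLayer(triggers=[EventTrigger(5, "X")]))
    with pytest.raises(CorpusError):
        doc.validate()


def test_document_validate_rejects_duplicate_trigger_anchor():
    tokens = [_tok(0, 0, None, "ROOT"), _tok(1, 0, 0)]
    layer = AnnotationLayer(triggers=[EventTrigger(0, "A"), EventTrigger(0, "B")])
    with pytest.raises(CorpusError):
        Document("d", tokens, gold=layer).validate()


# -- anchor tokens -----------------------------------------------------------


def test_anchor_token_of_np_span(fig_doc):
    # "The IRF-2 promoter region": head of 4 is 6 (outside) -> anchor is 4
    assert anchor_token([1, 2, 3, 4], fig_doc) == 4


def test_anchor_token_singleton(fig_doc):
    assert anchor_token([15], fig_doc) == 15


def test_anchor_token_empty_span(fig_doc):
    with pytest.raises(CorpusError):
        anchor_token([], fig_doc)


def test_anchor_token_rejects_cross_sentence_span(fig_doc):
    with pytest.raises(CorpusError):
        anchor_token([9, 10], fig_doc)


def test_anchor_token_broken_subtree_is_leftmost_exit(fig_doc):
    # tokens 2 and 5 are not a connected subtree: both heads exit the span;
    # the leftmost qualifying token wins
    assert anchor_token([2, 5], fig_doc) == 2


# -- entity clusters ---------------------------------------------------------


def test_coref_closure_merges_chains():
    clusters = coref_closure([CoreferenceLink(5, 2), CoreferenceLink(9, 5)])
    assert clusters.cluster_of(2) == frozenset({2, 5, 9})
    assert clusters.mates(5) == frozenset({2, 9})
    assert clusters.is_clustered(9)
    assert not clusters.is_clustered(7)
    assert clusters.cluster_of(7) == frozenset({7})


def test_coref_closure_pairs_are_symmetric():
    clusters = coref_closure([CoreferenceLink(5, 2)])
    assert clusters.pairs() == {(2, 5), (5, 2)}


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 30), st.integers(0, 30)).filter(lambda p: p[0] != p[1]),
        max_size=25,
    )
)
def test_coref_closure_matches_connected_components(pairs):
    # oracle: clusters are exactly the connected components of the link graph
    links = [CoreferenceLink(max(a, b), min(a, b)) for a, b in pairs]
    clusters = EntityClusters(links)
    g = nx.Graph()
    g.add_edges_from((l.anaphor, l.antecedent) for l in links)
    components = {frozenset(c) for c in nx.connected_components(g)}
    mentioned = {n for l in links for n in (l.anaphor, l.antecedent)}
    assert {clusters.cluster_of(n) for n in mentioned} == components


# -- link categories (worked-example structure) -------------------------------


def test_categorize_links_of_worked_example(fig_doc):
    clusters = coref_closure(fig_doc.gold.corefs)
    cats = {
        (l.event_anchor, l.arg_anchor): categorize_link(l, clusters, fig_doc)
        for l in fig_doc.gold.roles
    }
    assert cats[(13, 4)] is LinkCategory.CROSS
    assert cats[(13, 11)] is LinkCategory.W_ANT
    assert cats[(13, 15)] is LinkCategory.NORMAL


# -- candidate arguments -----------------------------------------------------


def test_candidate_arguments_without_coref_is_sentence_only(fig_doc):
    clusters = coref_closure([])
    assert candidate_arguments(1, fig_doc, clusters) == set(range(10, 17))


def test_candidate_arguments_with_coref_adds_antecedent(fig_doc):
    clusters = coref_closure(fig_doc.gold.corefs)
    assert candidate_arguments(1, fig_doc, clusters) == set(range(10, 17)) | {4}


def test_candidate_arguments_never_adds_later_tokens(fig_doc):
    # the closure is symmetric, but only *earlier*-sentence mates qualify
    clusters = coref_closure(fig_doc.gold.corefs)
    assert candidate_arguments(0, fig_doc, clusters) == set(range(0, 10))
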