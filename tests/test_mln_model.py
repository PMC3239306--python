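import pytest

from coreflink.corpus import coref_closure
from coreflink.evaluation import score
from coreflink.mln_core import hard_satisfied, map_infer
from coreflink.mln_model import (
    MLNModel,
    ModelSpec,
    PRESETS,
    SpecError,
    ground_documents,
    ground_sentence,
    predict_mln,
    train_mln,
)

SPEC = ModelSpec.from_preset("full", ("Regulation",))


def _ground_fig(fig_doc, preset="full", with_coref=True):
    spec = ModelSpec.from_preset(preset, ("Regulation",))
    clusters = coref_closure(fig_doc.gold.corefs if with_coref else [])
    return ground_sentence(fig_doc, 1, spec, clusters, frozenset())


def test_presets_and_spec_validation():
    assert ModelSpec.from_preset("baseline", ("A",)).coref_formulae == frozenset()
    assert ModelSpec.from_preset("full", ("A",)).coref_formulae == {"fc", "sid", "t"}
    with pytest.raises(SpecError):
        ModelSpec.from_preset("everything", ("A",))
    with pytest.raises(SpecError):
        ModelSpec(("A",), frozenset({"quantum"}))


def test_grounding_without_coref_has_no_cross_atoms(fig_doc):
    inst = _ground_fig(fig_doc, with_coref=False)
    assert all(a[2] >= 10 for a in inst.network.hidden if a[0] == "role")


def test_grounding_with_coref_adds_antecedent_atom(fig_doc):
    inst = _ground_fig(fig_doc)
    assert ("role", 13, 4, "Theme") in inst.network.hidden


def test_cross_atoms_carry_only_the_prior(fig_doc):
    inst = _ground_fig(fig_doc, preset="baseline")
    cross = ("role", 13, 4, "Theme")
    keys = [
        f.key
        for f in inst.network.factors
        if not f.hard and len(f.literals) == 1 and f.literals[0][0] == cross
    ]
    assert keys == [("xsent", "Theme")]


def test_coref_formula_factors_follow_preset(fig_doc):
    by_preset = {
        name: {f.key[0] for f in _ground_fig(fig_doc, preset=name).network.factors if not f.hard}
        for name in PRESETS
    }
    assert "t" not in by_preset["baseline"] and "sid" not in by_preset["baseline"]
    assert "t" in by_preset["full"] and "sid" in by_preset["full"] and "fc" in by_preset["full"]
    assert "t" not in by_preset["fc_sid"] and "sid" in by_preset["fc_sid"]
    assert "t" in by_preset["fc_t"] and "sid" not in by_preset["fc_t"]


def test_gold_assignment_satisfies_hard_constraints(fig_doc, small_corpus):
    inst = _ground_fig(fig_doc)
    assert hard_satisfied(inst.network, inst.gold)
    spec = ModelSpec.from_preset("full", ("Expression", "Binding", "Regulation"))
    for instance in ground_documents(small_corpus[:5], spec, "gold", frozenset()):
        assert hard_satisfied(instance.network, instance.gold)


def test_worked_example_transitivity_licenses_cross_link(fig_doc):
    """With hand-set weights, the cross-sentence Theme role(13,4) is
    predicted exactly when the Transitivity formula has positive weight."""
    inst = _ground_fig(fig_doc)
    weights = {
        ("evt", "word=inducible"): 2.0,
        ("etype", "word=inducible|Regulation"): 2.0,
        ("link", "dep=nsubj|Theme"): 2.0,
        ("link", "dep=nmod|Cause"): 2.0,
        ("xsent", "Theme"): -0.5,
        ("t", None): 1.0,
    }
    out = map_infer(inst.network, weights)
    assert out[("event", 13)]
    assert out[("eventType", 13, "Regulation")]
    assert out[("role", 13, 11, "Theme")]
    assert out[("role", 13, 15, "Cause")]
    assert out[("role", 13, 4, "Theme")]  # licensed by T through corefer(11,4)

    weights[("t", None)] = 0.0
    out = map_infer(inst.network, weights)
    assert out[("role", 13, 11, "Theme")]
    assert not out[("role", 13, 4, "Theme")]  # no T, no cross-link


def test_train_and_predict_respect_hard_constraints(small_corpus):
    model = train_mln(small_corpus[:15], preset="full", coref_mode="gold",
                      epochs=2, seed=0)
    for doc in small_corpus[15:20]:
        predict_mln(doc, model, coref_mode="gold")
        typed = {t.anchor for t in doc.pred.triggers}
        themed = {r.event_anchor for r in doc.pred.roles if r.role == "Theme"}
        for trig in doc.pred.triggers:
            assert trig.anchor in themed  # every event carries a Theme
        for role in doc.pred.roles:
            assert role.event_anchor in typed  # roles attach to typed events


def test_mln_without_coref_never_crosses_sentences(small_corpus):
    model = train_mln(small_corpus[:15], preset="baseline", coref_mode="none",
                      epochs=2, seed=0)
    for doc in small_corpus[15:20]:
        predict_mln(doc, model, coref_mode="none")
        for link in doc.pred.roles:
            assert doc.sentence_of(link.event_anchor) == doc.sentence_of(link.arg_anchor)


def test_model_round_trip(tmp_path, small_corpus):
    model = train_mln(small_corpus[:10], preset="full", coref_mode="gold",
                      epochs=1, seed=0)
    path = tmp_path / "mln.pkl"
    model.save(path)
    back = MLNModel.load(path)
    doc = small_corpus[10]
    predict_mln(doc, model, coref_mode="gold")
    expected = (list(doc.pred.triggers), list(doc.pred.roles))
    predict_mln(doc, back, coref_mode="gold")
    assert (doc.pred.triggers, doc.pred.roles) == expected
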