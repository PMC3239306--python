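"""Two-phase classifier pipeline with transitivity post-processing.

Phase 1 labels every token with an event type or ``Not-Event`` (a multiclass
linear max-margin classifier over simple token features).  Phase 2 labels
every (trigger, candidate-argument) pair within a sentence as Theme, Cause,
or None; candidates are NE-tagged tokens and other triggers.  Both phases
are strictly intra-sentence.  Cross-sentence links are produced afterwards
by a deterministic post-processing step that propagates each argument's
role to all of its coreference antecedents — so with no coreference layer
the pipeline structurally cannot emit a cross-link.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import LinearSVC


def _csr32(X):
    # liblinear requires 32-bit sparse indices
    X = X.tocsr()
    X.indices = X.indices.astype(np.int32)
    X.indptr = X.indptr.astype(np.int32)
    return X

from .corpus import (
    Document,
    EntityClusters,
    EventTrigger,
    RoleLink,
    coref_closure,
)
from .features import (
    FeatureVector,
    build_event_dictionary,
    copy_features,
    link_features,
    token_features,
)

NOT_EVENT = "Not-Event"
NO_ROLE = "None"
CorefMode = Literal["none", "gold", "sys"]

MODEL_FORMAT_VERSION = 1


def coref_layer(doc: Document, mode: CorefMode):
    if mode == "none":
        return []
    if mode == "gold":
        return doc.gold.corefs
    if mode == "sys":
        return doc.pred.corefs
    raise ValueError(f"unknown coreference mode {mode!r}")


# -- transitivity post-processing -------------------------------------------


def propagate_transitivity(
    links: Iterable[RoleLink], clusters: EntityClusters
) -> set[RoleLink]:
    """Attach every antecedent of each argument with the argument's role.

    For each link (e, a, r) and each cluster mate b of a that precedes a in
    the document, adds (e, b, r).  The cluster relation is already closed,
    so one pass reaches the whole chain; the operation is idempotent and
    monotone in the coreference layer.
    """
    out = set(links)
    for link in list(out):
        for mate in clusters.mates(link.arg_anchor):
            if mate < link.arg_anchor and mate != link.event_anchor:
                out.add(RoleLink(link.event_anchor, mate, link.role))
    return out


# -- models -----------------------------------------------------------------


@dataclass
class PipelineModel:
    event_types: tuple[str, ...]
    lexicon: frozenset[str]
    vec1: DictVectorizer
    clf1: LinearSVC
    vec2: DictVectorizer
    clf2: LinearSVC
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"format_version": MODEL_FORMAT_VERSION, "model": self}, fh)

    @staticmethod
    def load(path) -> "PipelineModel":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        if blob.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {blob.get('format_version')}")
        return blob["model"]


def _phase2_candidates(doc: Document, sentence: int, trigger_anchors: set[int]) -> list[int]:
    """NE-tagged tokens plus triggers of the sentence, in position order."""
    out = []
    for i in doc.sentence_span(sentence):
        if doc.tokens[i].ne != "O" or i in trigger_anchors:
            out.append(i)
    return out


def _pair_vector(
    e: int,
    a: int,
    doc: Document,
    lexicon: frozenset[str],
    clusters: EntityClusters | None,
) -> FeatureVector:
    vec: FeatureVector = {}
    for name, cnt in token_features(e, doc, lexicon).items():
        vec[f"E:{name}"] = cnt
    for name, cnt in token_features(a, doc, lexicon).items():
        vec[f"A:{name}"] = cnt
    vec.update(link_features(e, a, doc))
    if clusters is not None:
        vec.update(copy_features(a, clusters, doc))
    return vec


def train_pipeline(
    docs: Sequence[Document],
    coref_mode: CorefMode = "none",
    event_types: Sequence[str] | None = None,
    C: float = 1.0,
    seed: int = 0,
) -> PipelineModel:
    """Train both phases on gold annotations.

    Phase 2 is trained on gold triggers (the standard pipeline protocol);
    with a coreference mode other than ``none``, copied antecedent features
    are added to each candidate argument's representation.
    """
    if event_types is None:
        event_types = sorted(
            {t.event_type for doc in docs for t in doc.gold.triggers}
        )
    lexicon = build_event_dictionary(docs)

    x1, y1, x2, y2 = [], [], [], []
    for doc in docs:
        clusters = (
            coref_closure(coref_layer(doc, coref_mode)) if coref_mode != "none" else None
        )
        gold_types = {t.anchor: t.event_type for t in doc.gold.triggers}
        for tok in doc.tokens:
            x1.append(token_features(tok.doc_index, doc, lexicon))
            y1.append(gold_types.get(tok.doc_index, NOT_EVENT))
        gold_roles = {
            (r.event_anchor, r.arg_anchor): r.role for r in doc.gold.roles
        }
        trigger_anchors = set(gold_types)
        for s in range(doc.n_sentences()):
            cands = _phase2_candidates(doc, s, trigger_anchors)
            for e in doc.sentence_span(s):
                if e not in trigger_anchors:
                    continue
                for a in cands:
                    if a == e:
                        continue
                    x2.append(_pair_vector(e, a, doc, lexicon, clusters))
                    y2.append(gold_roles.get((e, a), NO_ROLE))

    vec1, vec2 = DictVectorizer(), DictVectorizer()
    clf1 = LinearSVC(C=C, random_state=seed)
    clf2 = LinearSVC(C=C, random_state=seed)
    clf1.fit(_csr32(vec1.fit_transform(x1)), y1)
    clf2.fit(_csr32(vec2.fit_transform(x2)), y2)
    return PipelineModel(
        event_types=tuple(event_types),
        lexicon=lexicon,
        vec1=vec1,
        clf1=clf1,
        vec2=vec2,
        clf2=clf2,
        meta={"coref_mode": coref_mode, "C": C, "seed": seed},
    )


def phase1_predict(doc: Document, model: PipelineModel) -> list[EventTrigger]:
    """Label every token; non-``Not-Event`` labels become triggers."""
    feats = [token_features(i, doc, model.lexicon) for i in range(len(doc.tokens))]
    if not feats:
        return []
    labels = model.clf1.predict(_csr32(model.vec1.transform(feats)))
    return [
        EventTrigger(i, lab)
        for i, lab in enumerate(labels)
        if lab != NOT_EVENT
    ]


def phase2_predict(
    doc: Document,
    triggers: Sequence[EventTrigger],
    model: PipelineModel,
    clusters: EntityClusters | None = None,
) -> list[RoleLink]:
    """Label all intra-sentence (trigger, candidate) pairs; keep Theme/Cause."""
    trigger_anchors = {t.anchor for t in triggers}
    pairs: list[tuple[int, int]] = []
    feats: list[FeatureVector] = []
    for s in range(doc.n_sentences()):
        cands = _phase2_candidates(doc, s, trigger_anchors)
        for e in doc.sentence_span(s):
            if e not in trigger_anchors:
                continue
            for a in cands:
                if a == e:
                    continue
                pairs.append((e, a))
                feats.append(_pair_vector(e, a, doc, model.lexicon, clusters))
    if not pairs:
        return []
    labels = model.clf2.predict(_csr32(model.vec2.transform(feats)))
    return [
        RoleLink(e, a, lab)
        for (e, a), lab in zip(pairs, labels)
        if lab != NO_ROLE
    ]


def predict_pipeline(
    doc: Document, model: PipelineModel, coref_mode: CorefMode = "none"
) -> None:
    """Run both phases plus transitivity; writes the document's pred layer."""
    links = coref_layer(doc, coref_mode)
    clusters = coref_closure(links) if links else None
    triggers = phase1_predict(doc, model)
    roles = phase2_predict(
        doc, triggers, model, clusters if coref_mode != "none" else None
    )
    if clusters is not None:
        roles = sorted(propagate_transitivity(roles, clusters))
    doc.pred.triggers = list(triggers)
    doc.pred.roles = sorted(roles)
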