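"""Document/annotation data model for event-argument relation extraction.

Biomedical event extraction links *event triggers* (often nominalised, e.g.
"induction", "binding") to their arguments via Theme/Cause role links.  The
model here keeps one flat, document-global token index space so that
relations crossing sentence boundaries (cross-links) are first-class: a role
link or coreference link is just a pair of document-global token positions.

Phrasal mentions are represented by their *anchor token*: the root of the
phrase's dependency subtree.  All annotation layers (triggers, role links,
coreference links) reference anchor tokens only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

ROLES = ("Theme", "Cause")


class CorpusError(ValueError):
    """Invariant violation in a document or annotation layer."""


@dataclass
class Token:
    doc_index: int
    sentence_index: int
    word: str
    stem: str
    pos: str
    ne: str
    chunk: str
    head: int | None  # doc_index of dependency head; None for sentence root
    dep_label: str


@dataclass(frozen=True)
class EventTrigger:
    anchor: int
    event_type: str


@dataclass(frozen=True, order=True)
class RoleLink:
    event_anchor: int
    arg_anchor: int
    role: str

    def __post_init__(self):
        if self.event_anchor == self.arg_anchor:
            raise CorpusError("role link must connect two distinct tokens")
        if self.role not in ROLES:
            raise CorpusError(f"unknown role {self.role!r}; expected one of {ROLES}")


@dataclass(frozen=True, order=True)
class CoreferenceLink:
    anaphor: int
    antecedent: int

    def __post_init__(self):
        if self.antecedent >= self.anaphor:
            raise CorpusError(
                f"antecedent {self.antecedent} must precede anaphor {self.anaphor}"
            )


class LinkCategory(enum.Enum):
    CROSS = "Cross"
    W_ANT = "W-ANT"
    NORMAL = "Normal"


@dataclass
class AnnotationLayer:
    """One set of trigger/role/coreference annotations (gold or predicted)."""

    triggers: list[EventTrigger] = field(default_factory=list)
    roles: list[RoleLink] = field(default_factory=list)
    corefs: list[CoreferenceLink] = field(default_factory=list)

    def copy(self) -> "AnnotationLayer":
        return AnnotationLayer(list(self.triggers), list(self.roles), list(self.corefs))


@dataclass
class Document:
    doc_id: str
    tokens: list[Token]
    gold: AnnotationLayer = field(default_factory=AnnotationLayer)
    pred: AnnotationLayer = field(default_factory=AnnotationLayer)

    # -- structure ---------------------------------------------------------

    def n_sentences(self) -> int:
        return self.tokens[-1].sentence_index + 1 if self.tokens else 0

    def sentence_span(self, s: int) -> range:
        """Doc-index range of sentence ``s``."""
        idx = [t.doc_index for t in self.tokens if t.sentence_index == s]
        if not idx:
            raise CorpusError(f"document {self.doc_id} has no sentence {s}")
        return range(idx[0], idx[-1] + 1)

    def sentence_of(self, i: int) -> int:
        return self.tokens[i].sentence_index

    def sentence_root(self, s: int) -> int:
        for i in self.sentence_span(s):
            if self.tokens[i].head is None:
                return i
        raise CorpusError(f"sentence {s} of {self.doc_id} has no root")

    def validate(self) -> None:
        n = len(self.tokens)
        prev_sent = 0
        for i, tok in enumerate(self.tokens):
            if tok.doc_index != i:
                raise CorpusError(f"token {i} carries doc_index {tok.doc_index}")
            if tok.sentence_index < prev_sent:
                raise CorpusError("sentence_index must be non-decreasing")
            prev_sent = tok.sentence_index
            if tok.head is not None:
                if not 0 <= tok.head < n:
                    raise CorpusError(f"token {i}: head {tok.head} out of range")
                if self.tokens[tok.head].sentence_index != tok.sentence_index:
                    raise CorpusError(f"token {i}: head crosses sentence boundary")
        for s in range(self.n_sentences()):
            span = self.sentence_span(s)
            roots = [i for i in span if self.tokens[i].head is None]
            if len(roots) != 1:
                raise CorpusError(f"sentence {s} has {len(roots)} roots, expected 1")
            # acyclicity: walk each token to the root
            for i in span:
                seen, j = set(), i
                while self.tokens[j].head is not None:
                    if j in seen:
                        raise CorpusError(f"dependency cycle at token {i}")
                    seen.add(j)
                    j = self.tokens[j].head
        for layer in (self.gold, self.pred):
            anchors = {t.anchor for t in layer.triggers}
            if len(anchors) != len(layer.triggers):
                raise CorpusError("multiple triggers share an anchor token")
            for t in layer.triggers:
                self._check_index(t.anchor)
            for r in layer.roles:
                self._check_index(r.event_anchor)
                self._check_index(r.arg_anchor)
            for c in layer.corefs:
                self._check_index(c.anaphor)
                self._check_index(c.antecedent)

    def _check_index(self, i: int) -> None:
        if not 0 <= i < len(self.tokens):
            raise CorpusError(f"annotation anchor {i} out of range in {self.doc_id}")


# -- anchor tokens ----------------------------------------------------------


def anchor_token(span: Sequence[int], doc: Document) -> int:
    """Anchor of a phrasal span: the token whose dependency head exits the span.

    The anchor stands in for the whole phrase in every annotation layer.  If
    the parse makes several tokens qualify (a broken subtree), the leftmost
    qualifying token wins, which keeps the choice deterministic.
    """
    span = sorted(span)
    if not span:
        raise CorpusError("empty span has no anchor")
    sents = {doc.tokens[i].sentence_index for i in span}
    if len(sents) > 1:
        raise CorpusError("anchor span crosses a sentence boundary")
    inside = set(span)
    for i in span:
        head = doc.tokens[i].head
        if head is None or head not in inside:
            return i
    raise CorpusError("span contains a dependency cycle")


# -- coreference closure ----------------------------------------------------


class EntityClusters:
    """Partition of mentioned tokens into entity clusters.

    The symmetric-transitive closure of the anaphor->antecedent links:
    connected components of the undirected link graph.  Tokens never
    mentioned in any link are implicit singletons.
    """

    def __init__(self, links: Iterable[CoreferenceLink]):
        parent: dict[int, int] = {}

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for link in links:
            for node in (link.anaphor, link.antecedent):
                parent.setdefault(node, node)
            ra, rb = find(link.anaphor), find(link.antecedent)
            if ra != rb:
                parent[ra] = rb
        groups: dict[int, set[int]] = {}
        for node in parent:
            groups.setdefault(find(node), set()).add(node)
        self._cluster_of: dict[int, frozenset[int]] = {}
        for members in groups.values():
            fs = frozenset(members)
            for node in fs:
                self._cluster_of[node] = fs

    def cluster_of(self, i: int) -> frozenset[int]:
        return self._cluster_of.get(i, frozenset((i,)))

    def mates(self, i: int) -> frozenset[int]:
        """Cluster members other than ``i`` itself."""
        return self.cluster_of(i) - {i}

    def is_clustered(self, i: int) -> bool:
        return len(self.cluster_of(i)) > 1

    def clusters(self) -> list[frozenset[int]]:
        return list({id(c): c for c in self._cluster_of.values()}.values())

    def pairs(self) -> set[tuple[int, int]]:
        """Symmetric closure of the cluster relation as ordered pairs."""
        out: set[tuple[int, int]] = set()
        for c in self.clusters():
            mem = sorted(c)
            for a in mem:
                for b in mem:
                    if a != b:
                        out.add((a, b))
        return out


def coref_closure(links: Iterable[CoreferenceLink]) -> EntityClusters:
    """Entity clusters as the symmetric-transitive closure of the links."""
    return EntityClusters(links)


# -- link categories --------------------------------------------------------


def categorize_link(link: RoleLink, clusters: EntityClusters, doc: Document) -> LinkCategory:
    """Cross (spans sentences), W-ANT (intra, argument has cluster mates), Normal."""
    if doc.sentence_of(link.event_anchor) != doc.sentence_of(link.arg_anchor):
        return LinkCategory.CROSS
    if clusters.is_clustered(link.arg_anchor):
        return LinkCategory.W_ANT
    return LinkCategory.NORMAL


# -- candidate arguments ----------------------------------------------------


def candidate_arguments(sentence: int, doc: Document, clusters: EntityClusters) -> set[int]:
    """Argument candidates for events of one sentence.

    All tokens of the sentence, plus every earlier-sentence token that is a
    cluster mate (antecedent) of some token in the sentence.  With no
    coreference information the candidate set is exactly the sentence — which
    is what makes cross-links structurally unreachable without coreference.
    """
    span = doc.sentence_span(sentence)
    out = set(span)
    for i in span:
        for mate in clusters.mates(i):
            if doc.sentence_of(mate) < sentence:
                out.add(mate)
    return out
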