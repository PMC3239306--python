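"""Local feature extraction for triggers and event-argument pairs.

Features come in two families, mirroring how they are consumed downstream:

* *simple token properties* — word form, POS, stem, NE tag, chunk tag,
  event-dictionary membership, character-class flags, and character n-grams
  of a single token;
* *link token properties* — the dependency relation between two tokens of
  one sentence: direct dependency label, labeled and unlabeled shortest
  dependency paths, and the least common ancestor on that path.

Feature vectors are plain ``dict[str, int]`` mappings from a
``template=value`` atom to its count.  *Feature copy* augments an anaphoric
token with the simple features of its earlier cluster mates under a
``copied:`` namespace, so a learner can weight copied evidence separately
from the token's own evidence.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable

from .corpus import Document, EntityClusters

FeatureVector = dict[str, int]


class CrossSentenceError(ValueError):
    """Dependency-path features are defined within one sentence only."""


def _add(vec: FeatureVector, name: str, value: str = "") -> None:
    key = f"{name}={value}" if value else name
    vec[key] = vec.get(key, 0) + 1


def build_event_dictionary(docs: Iterable[Document]) -> frozenset[str]:
    """Lexicon of gold trigger stems, collected from training documents."""
    stems = set()
    for doc in docs:
        for trig in doc.gold.triggers:
            stems.add(doc.tokens[trig.anchor].stem)
    return frozenset(stems)


def character_ngrams(word: str, n: int) -> list[str]:
    """Character n-grams of the surface form, no boundary markers."""
    return [word[k : k + n] for k in range(len(word) - n + 1)]


def token_features(i: int, doc: Document, lexicon: frozenset[str] = frozenset()) -> FeatureVector:
    """Simple token properties of token ``i``."""
    tok = doc.tokens[i]
    vec: FeatureVector = {}
    _add(vec, "word", tok.word)
    _add(vec, "pos", tok.pos)
    _add(vec, "stem", tok.stem)
    _add(vec, "ne", tok.ne)
    _add(vec, "chunk", tok.chunk)
    if tok.stem in lexicon:
        _add(vec, "dict")
    if any(ch.isupper() for ch in tok.word):
        _add(vec, "capital")
    if any(ch.isdigit() for ch in tok.word):
        _add(vec, "numeric")
    if any(not ch.isalnum() for ch in tok.word):
        _add(vec, "punc")
    for bi in character_ngrams(tok.word, 2):
        _add(vec, "bigram", bi)
    for tri in character_ngrams(tok.word, 3):
        _add(vec, "trigram", tri)
    return vec


# -- dependency paths -------------------------------------------------------


def _depth(i: int, doc: Document) -> int:
    d, j = 0, i
    while doc.tokens[j].head is not None:
        j = doc.tokens[j].head
        d += 1
    return d


def dependency_path(i: int, j: int, doc: Document) -> tuple[str, str, int]:
    """Shortest dependency path between two tokens of one sentence.

    Returns ``(labeled, unlabeled, lca)``: the labeled path renders each hop
    as an arrow toward (``↑label``) or away from (``↓label``) the root; the
    unlabeled variant keeps arrows only; ``lca`` is the topmost token on the
    path (the two tokens' least common ancestor).
    """
    if doc.sentence_of(i) != doc.sentence_of(j):
        raise CrossSentenceError(f"tokens {i} and {j} lie in different sentences")
    if i == j:
        return "", "", i
    span = doc.sentence_span(doc.sentence_of(i))
    # undirected adjacency with hop rendering
    adj: dict[int, list[tuple[int, str, str]]] = {k: [] for k in span}
    for k in span:
        head = doc.tokens[k].head
        if head is not None:
            lab = doc.tokens[k].dep_label
            adj[k].append((head, f"↑{lab}", "↑"))
            adj[head].append((k, f"↓{lab}", "↓"))
    prev: dict[int, tuple[int, str, str]] = {}
    queue = deque([i])
    seen = {i}
    while queue:
        cur = queue.popleft()
        if cur == j:
            break
        for nxt, lab, arrow in adj[cur]:
            if nxt not in seen:
                seen.add(nxt)
                prev[nxt] = (cur, lab, arrow)
                queue.append(nxt)
    if j not in prev:
        raise CrossSentenceError(f"no dependency path between {i} and {j}")
    hops: list[tuple[str, str]] = []
    nodes = [j]
    cur = j
    while cur != i:
        cur, lab, arrow = prev[cur]
        hops.append((lab, arrow))
        nodes.append(cur)
    hops.reverse()
    nodes.reverse()
    lca = min(nodes, key=lambda n: _depth(n, doc))
    labeled = "".join(lab for lab, _ in hops)
    unlabeled = "".join(arrow for _, arrow in hops)
    return labeled, unlabeled, lca


def link_features(i: int, j: int, doc: Document) -> FeatureVector:
    """Link token properties for the ordered pair (event ``i``, argument ``j``)."""
    vec: FeatureVector = {}
    if doc.tokens[j].head == i:
        _add(vec, "dep", doc.tokens[j].dep_label)
    if doc.tokens[i].head == j:
        _add(vec, "dep", f"inv:{doc.tokens[i].dep_label}")
    labeled, unlabeled, lca = dependency_path(i, j, doc)
    _add(vec, "path", labeled)
    _add(vec, "pathNL", unlabeled)
    _add(vec, "lca", doc.tokens[lca].pos)
    return vec


# -- feature copy -----------------------------------------------------------


def _subtree_children(k: int, doc: Document) -> list[int]:
    return [t.doc_index for t in doc.tokens if t.head == k]


def copy_features(j: int, clusters: EntityClusters, doc: Document) -> FeatureVector:
    """Features of token ``j``'s earlier cluster mates, namespaced ``copied:``.

    For every cluster mate ``k`` preceding ``j``, the word/POS/NE of ``k``
    and of ``k``'s direct dependency children are emitted as copied features
    of ``j``.  Unclustered tokens get an empty vector.
    """
    vec: FeatureVector = {}
    for k in sorted(clusters.mates(j)):
        if k >= j:
            continue
        for node in [k] + _subtree_children(k, doc):
            tok = doc.tokens[node]
            _add(vec, "copied:word", tok.word)
            _add(vec, "copied:pos", tok.pos)
            _add(vec, "copied:ne", tok.ne)
    return vec
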