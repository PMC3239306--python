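"""Pairwise noun-phrase coreference resolution, tuned for precision.

Every ordered pair of NP heads (earlier, later) within a sentence window is
classified as coreferent or not with a linear max-margin model over basic
features (word/stem match, NE and POS tag pairs, distances, substring and
acronym cues).  Because the downstream event extractors are hurt far more
by spurious chains than by missed ones, the operating point is chosen
precision-first: the positive class is cost-weighted and the decision
threshold is selected on a development split as the lowest threshold whose
precision still clears the target (0.9 by default), maximizing recall
subject to that.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import LinearSVC

from .corpus import CoreferenceLink, Document, coref_closure
from .pipeline import _csr32
from .features import FeatureVector

MODEL_FORMAT_VERSION = 1


class DegenerateDataError(ValueError):
    """Training data with a single class cannot fit a pairwise model."""


@dataclass(frozen=True)
class MentionPair:
    doc_id: str
    antecedent: int
    anaphor: int
    features: tuple[tuple[str, int], ...]
    label: bool


@dataclass
class PairwiseModel:
    vec: DictVectorizer
    clf: LinearSVC
    threshold: float
    pos_cost: float
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"format_version": MODEL_FORMAT_VERSION, "model": self}, fh)

    @staticmethod
    def load(path) -> "PairwiseModel":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        if blob.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {blob.get('format_version')}")
        return blob["model"]


# -- mentions and pairs -----------------------------------------------------


def extract_mentions(doc: Document) -> list[int]:
    """Head token (rightmost token) of every NP chunk, in document order."""
    heads = []
    n = len(doc.tokens)
    for i, tok in enumerate(doc.tokens):
        if not tok.chunk.endswith("NP"):
            continue
        nxt = doc.tokens[i + 1] if i + 1 < n else None
        chunk_continues = (
            nxt is not None
            and nxt.sentence_index == tok.sentence_index
            and nxt.chunk == "I-NP"
        )
        if not chunk_continues:
            heads.append(i)
    return heads


def pair_features(b: int, a: int, doc: Document) -> FeatureVector:
    """Basic features of the ordered mention pair (antecedent b, anaphor a)."""
    tb, ta = doc.tokens[b], doc.tokens[a]
    vec: FeatureVector = {}
    if ta.word == tb.word:
        vec["word_match"] = 1
    if ta.stem == tb.stem:
        vec["stem_match"] = 1
    wa, wb = ta.word.lower(), tb.word.lower()
    if wa != wb and (wa in wb or wb in wa):
        vec["substring"] = 1
    caps_b = "".join(ch for ch in tb.word if ch.isupper())
    if len(wa) >= 2 and wa.upper() == caps_b and len(caps_b) >= 2:
        vec["acronym"] = 1
    vec[f"ne_pair={tb.ne}|{ta.ne}"] = 1
    vec[f"pos_pair={tb.pos}|{ta.pos}"] = 1
    sent_dist = min(ta.sentence_index - tb.sentence_index, 3)
    vec[f"sent_dist={sent_dist}"] = 1
    vec["tok_dist_log"] = int(np.log1p(a - b))
    return vec


def generate_pairs(
    doc: Document, window: int | None = None, gold: bool = True
) -> list[MentionPair]:
    """All ordered (earlier, later) NP-head pairs within the sentence window.

    With ``gold`` the pairs are labeled from the closure of the document's
    gold coreference layer (cluster mates are positive).
    """
    mentions = extract_mentions(doc)
    clusters = coref_closure(doc.gold.corefs) if gold else None
    pairs = []
    for k, a in enumerate(mentions):
        for b in mentions[:k]:
            if window is not None:
                if doc.sentence_of(a) - doc.sentence_of(b) > window:
                    continue
            label = bool(clusters and b in clusters.mates(a))
            pairs.append(
                MentionPair(
                    doc_id=doc.doc_id,
                    antecedent=b,
                    anaphor=a,
                    features=tuple(sorted(pair_features(b, a, doc).items())),
                    label=label,
                )
            )
    return pairs


# -- training ---------------------------------------------------------------


def train_pairwise(
    pairs: Sequence[MentionPair],
    dev_pairs: Sequence[MentionPair] | None = None,
    pos_cost: float = 10.0,
    target_precision: float = 0.9,
    C: float = 1.0,
    seed: int = 0,
) -> PairwiseModel:
    """Fit the pairwise classifier and select a precision-first threshold.

    The positive class carries a cost multiplier (the analogue of driving a
    margin-violation penalty very high for the rare class), and the decision
    threshold is swept on ``dev_pairs`` (or the training pairs if absent):
    the selected threshold is the one with the highest recall among those
    meeting the precision target, falling back to the most precise
    operating point when the target is unreachable.
    """
    labels = [p.label for p in pairs]
    if len(set(labels)) < 2:
        raise DegenerateDataError(
            "pairwise training needs both coreferent and non-coreferent pairs"
        )
    vec = DictVectorizer()
    X = _csr32(vec.fit_transform([dict(p.features) for p in pairs]))
    clf = LinearSVC(C=C, class_weight={True: pos_cost, False: 1.0}, random_state=seed)
    clf.fit(X, labels)

    sweep = dev_pairs if dev_pairs is not None else pairs
    scores = clf.decision_function(_csr32(vec.transform([dict(p.features) for p in sweep])))
    truth = np.array([p.label for p in sweep])
    threshold = _select_threshold(scores, truth, target_precision)
    return PairwiseModel(
        vec=vec,
        clf=clf,
        threshold=threshold,
        pos_cost=pos_cost,
        meta={"target_precision": target_precision, "C": C, "seed": seed},
    )


def _select_threshold(scores: np.ndarray, truth: np.ndarray, target: float) -> float:
    ranked = scores[np.argsort(-scores)]
    tp = np.cumsum(truth[np.argsort(-scores)])
    k = np.arange(1, len(scores) + 1)
    precision = tp / k
    # a threshold admits *every* pair scoring at or above it, so only cuts
    # at strict score boundaries are realizable — cutting inside a block of
    # tied scores would admit the whole block
    realizable = np.append(ranked[:-1] > ranked[1:], True)
    # a useful cut also ends on a coreferent pair: admitting trailing
    # non-coreferent pairs adds no recall and only costs precision
    ends_positive = truth[np.argsort(-scores)]
    ok = np.flatnonzero((precision >= target) & realizable & ends_positive)
    if len(ok) and tp[ok[-1]] > 0:
        # deepest cut (max recall) that still meets the precision target
        cut = int(ok[-1])
    elif tp[-1] == 0:
        return float(scores.max() + 1.0)  # nothing positive scoreable
    else:
        masked = np.where(realizable, precision, -1.0)
        cut = int(np.argmax(masked))
    return float(ranked[cut])


def resolve(doc: Document, model: PairwiseModel, window: int | None = None) -> list[CoreferenceLink]:
    """Link every pair scoring at or above the model's threshold."""
    pairs = generate_pairs(doc, window=window, gold=False)
    if not pairs:
        return []
    scores = model.clf.decision_function(
        _csr32(model.vec.transform([dict(p.features) for p in pairs]))
    )
    return sorted(
        CoreferenceLink(p.anaphor, p.antecedent)
        for p, s in zip(pairs, scores)
        if s >= model.threshold
    )


def pairwise_prf(
    gold_docs: Sequence[Document], pred_links: dict[str, list[CoreferenceLink]]
) -> tuple[float, float, float]:
    """Pairwise precision/recall/F1 of predicted links against gold clusters.

    A predicted link counts as correct when its two mentions share a gold
    cluster; gold positives are all cluster-mate pairs.
    """
    tp = fp = fn = 0
    for doc in gold_docs:
        clusters = coref_closure(doc.gold.corefs)
        gold_pairs = {(a, b) for (a, b) in clusters.pairs() if a > b}
        pred = {(l.anaphor, l.antecedent) for l in pred_links.get(doc.doc_id, [])}
        tp += len(pred & gold_pairs)
        fp += len(pred - gold_pairs)
        fn += len(gold_pairs - pred)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f
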