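"""Scoring, cross-validation folds, and exact significance testing.

Scores are exact-match precision/recall/F1 per hidden predicate (event,
eventType, role), with role links additionally broken down by link
category: Cross (sentence-crossing), W-ANT (intra-sentence with a
coreferent argument), and Normal.  Categories are always computed against
the *gold* coreference layer so that systems using different coreference
inputs are compared on the same category partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .corpus import Document, LinkCategory, categorize_link, coref_closure


class AlignmentError(ValueError):
    pass


@dataclass
class PRF:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def add(self, other: "PRF") -> None:
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


@dataclass
class CategoryReport:
    event: PRF = field(default_factory=PRF)
    event_type: PRF = field(default_factory=PRF)
    role: PRF = field(default_factory=PRF)
    by_category: dict[LinkCategory, PRF] = field(
        default_factory=lambda: {c: PRF() for c in LinkCategory}
    )

    def add(self, other: "CategoryReport") -> None:
        self.event.add(other.event)
        self.event_type.add(other.event_type)
        self.role.add(other.role)
        for c in LinkCategory:
            self.by_category[c].add(other.by_category[c])

    def as_dict(self) -> dict:
        return {
            "event": self.event.as_dict(),
            "eventType": self.event_type.as_dict(),
            "role": self.role.as_dict(),
            "role_by_category": {
                c.value: prf.as_dict() for c, prf in self.by_category.items()
            },
        }


def _set_prf(gold: set, pred: set) -> PRF:
    return PRF(tp=len(gold & pred), fp=len(pred - gold), fn=len(gold - pred))


def score(gold_docs: Sequence[Document], pred_docs: Sequence[Document]) -> CategoryReport:
    """Exact-match PRF per predicate, with the role breakdown by category.

    ``pred_docs`` carry predictions in their ``pred`` layer and are aligned
    to ``gold_docs`` by ``doc_id``; gold annotations are taken from
    ``gold_docs`` only.
    """
    pred_by_id = {d.doc_id: d for d in pred_docs}
    if set(pred_by_id) != {d.doc_id: None for d in gold_docs}.keys():
        raise AlignmentError("gold and predicted document sets have different doc_ids")
    report = CategoryReport()
    for gdoc in gold_docs:
        pdoc = pred_by_id[gdoc.doc_id]
        gold_ev = {t.anchor for t in gdoc.gold.triggers}
        pred_ev = {t.anchor for t in pdoc.pred.triggers}
        report.event.add(_set_prf(gold_ev, pred_ev))
        gold_et = {(t.anchor, t.event_type) for t in gdoc.gold.triggers}
        pred_et = {(t.anchor, t.event_type) for t in pdoc.pred.triggers}
        report.event_type.add(_set_prf(gold_et, pred_et))
        gold_roles = set(gdoc.gold.roles)
        pred_roles = set(pdoc.pred.roles)
        report.role.add(_set_prf(gold_roles, pred_roles))
        clusters = coref_closure(gdoc.gold.corefs)
        for c in LinkCategory:
            g = {l for l in gold_roles if categorize_link(l, clusters, gdoc) is c}
            p = {l for l in pred_roles if categorize_link(l, clusters, gdoc) is c}
            report.by_category[c].add(_set_prf(g, p))
    return report


def kfold(
    docs: Sequence[Document], k: int = 5, seed: int = 0
) -> list[tuple[list[Document], list[Document]]]:
    """Document-level k-fold partitions (train, test), deterministic by seed."""
    if len(docs) < k:
        raise ValueError(f"need at least {k} documents for {k}-fold splits, got {len(docs)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(docs))
    folds = np.array_split(order, k)
    out = []
    for f in folds:
        test_idx = set(int(i) for i in f)
        train = [d for i, d in enumerate(docs) if i not in test_idx]
        test = [d for i, d in enumerate(docs) if i in test_idx]
        out.append((train, test))
    return out


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-tailed McNemar test on the discordant-pair counts.

    ``b`` and ``c`` count the units one system got right and the other
    wrong; under the null they are Binomial(b+c, 1/2), and the two-tailed
    p-value is twice the smaller tail, clipped to 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * binom.cdf(min(b, c), n, 0.5)))


def discordant_counts(
    gold_docs: Sequence[Document],
    pred_a: dict[str, set],
    pred_b: dict[str, set],
) -> tuple[int, int]:
    """Per-link discordance between two systems for McNemar's test.

    Units are decisions on the union of gold links and either system's
    predictions: a unit is correct for a system iff the system's decision
    (link or no link) matches gold.
    """
    b = c = 0
    for doc in gold_docs:
        gold = set(doc.gold.roles)
        pa = pred_a.get(doc.doc_id, set())
        pb = pred_b.get(doc.doc_id, set())
        for link in gold | pa | pb:
            ok_a = (link in pa) == (link in gold)
            ok_b = (link in pb) == (link in gold)
            if ok_a and not ok_b:
                b += 1
            elif ok_b and not ok_a:
                c += 1
    return b, c
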