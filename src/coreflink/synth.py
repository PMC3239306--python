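"""Synthetic annotated corpora with controlled coreference structure.

The generator emulates the shape of a biomedical event corpus at the level
the extractors care about: documents of tagged, dependency-parsed sentences;
nominal and verbal event triggers drawn from type-specific vocabularies;
Theme/Cause role links (every event carries at least one Theme); entity NPs
with NE tags; coreference chains whose anaphors are event arguments; and
cross-sentence role links realized through those chains, plus a configurable
fraction of zero-anaphora cross-links that no chain can explain.

Two properties are deliberate, because they are what make the coreference
formulae *testable* rather than redundant:

* Anaphoric arguments attach to their trigger with ambiguous dependency
  labels (``nmod`` for Themes, ``nmod:agt`` for Causes) that distractor
  entities draw from uniformly, so token-local and link-local evidence
  alone cannot tell an anaphoric argument from a distractor — the label
  hints at the role type but never at argument-hood; only discourse
  salience (the mention being coreferent with earlier material) resolves
  the ambiguity, as it does in running text where anaphors are
  syntactically uninformative.
* Not every coreference chain marks an argument: appositive-style mentions
  corefer with earlier material without participating in any event, so the
  presence of an in-sentence anaphor does not by itself imply that its
  antecedent carries a cross-sentence role.

The vocabulary and the event-type inventory are invented — nothing here
imitates any real corpus's lexicon — but the *rates* (chains, cross-links,
zero-anaphora) are the dials the evaluation needs, and the entity
vocabulary is large enough that word forms seen at test time are mostly
novel, as protein names are.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .corpus import (
    AnnotationLayer,
    CoreferenceLink,
    Document,
    EventTrigger,
    RoleLink,
    Token,
)

DEFAULT_EVENT_TYPES = ("Expression", "Binding", "Regulation")

_TRIGGER_STEMS = {
    "Expression": ["exprind", "exprup", "exprsig", "exprlev"],
    "Binding": ["bindact", "bindcmp", "bindsite", "bindfrm"],
    "Regulation": ["regctl", "regmod", "regresp", "regdep"],
}
_FILLERS = [
    "the", "of", "in", "cells", "we", "observed", "that", "analysis",
    "results", "with", "for", "levels", "shown", "during", "response",
]


class ConfigError(ValueError):
    """Inconsistent generator configuration."""


@dataclass
class SyntheticConfig:
    """Knobs of the corpus simulator.

    ``cross_link_rate`` applies per event in a non-initial sentence; a cross
    link is zero-anaphora with probability ``zero_anaphora_fraction`` and is
    otherwise realized through a coreference chain on the event's Theme
    argument, whose antecedent sits in an earlier sentence.
    ``coref_chain_rate`` additionally gives Theme arguments a same-sentence
    antecedent, producing intra-sentence chains (and hence W-ANT links)
    independent of any cross link.  ``distractor_chain_rate`` emits
    appositive mentions that corefer with earlier-sentence material but
    play no role in any event — coreference that is *not* evidence of an
    argument.
    """

    n_docs: int = 50
    sentences_per_doc: tuple[int, int] = (2, 4)
    tokens_per_sentence: tuple[int, int] = (8, 12)
    event_types: tuple[str, ...] = DEFAULT_EVENT_TYPES
    trigger_rate: float = 0.9
    cause_rate: float = 0.5
    coref_chain_rate: float = 0.2
    cross_link_rate: float = 0.3
    zero_anaphora_fraction: float = 0.2
    distractor_chain_rate: float = 0.25
    noise_rate: float = 0.0
    n_protein_words: int = 20000
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "trigger_rate",
            "cause_rate",
            "coref_chain_rate",
            "cross_link_rate",
            "zero_anaphora_fraction",
            "distractor_chain_rate",
            "noise_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if (
            self.cross_link_rate > 0
            and self.coref_chain_rate == 0
            and self.zero_anaphora_fraction < 1
        ):
            raise ConfigError(
                "cross links require coreference chains unless every cross "
                "link is zero-anaphora (coref_chain_rate=0 demands "
                "zero_anaphora_fraction=1)"
            )
        for t in self.event_types:
            if t not in _TRIGGER_STEMS:
                raise ConfigError(f"no trigger vocabulary for event type {t!r}")


@dataclass
class _Mention:
    """An entity NP already emitted: doc_index of its head plus its word."""

    head: int
    word: str
    sentence: int


class _DocBuilder:
    def __init__(self, cfg: SyntheticConfig, rng: np.random.Generator, doc_id: str):
        self.cfg = cfg
        self.rng = rng
        self.doc_id = doc_id
        self.tokens: list[Token] = []
        self.layer = AnnotationLayer()
        self.mentions: list[_Mention] = []
        self.proteins = [f"PR{k}-{chr(65 + k % 26)}" for k in range(cfg.n_protein_words)]

    def _tok(self, sent: int, word: str, pos: str, ne: str, chunk: str,
             head: int | None, dep: str) -> int:
        i = len(self.tokens)
        self.tokens.append(
            Token(i, sent, word, word.lower(), pos, ne, chunk, head, dep)
        )
        return i

    def _entity_np(self, sent: int, attach: int | None, dep: str,
                   word: str | None = None) -> int:
        """Emit a determiner + protein-head NP; returns the head doc_index."""
        rng = self.rng
        if word is None:
            word = self.proteins[rng.integers(len(self.proteins))]
        det = self._tok(sent, "the", "DT", "O", "B-NP", None, "det")
        head = self._tok(sent, word, "NN", "PROTEIN", "I-NP", attach, dep)
        self.tokens[det].head = head
        self.mentions.append(_Mention(head, word, sent))
        return head

    def _trigger_word(self, etype: str) -> str:
        rng = self.rng
        if self.cfg.noise_rate > 0 and rng.random() < self.cfg.noise_rate:
            return _FILLERS[rng.integers(len(_FILLERS))]
        stems = _TRIGGER_STEMS[etype]
        return f"{stems[rng.integers(len(stems))]}{rng.integers(4)}"

    def build_sentence(self, sent: int) -> None:
        cfg, rng = self.cfg, self.rng
        has_event = rng.random() < cfg.trigger_rate
        earlier = [m for m in self.mentions if m.sentence < sent]

        if not has_event:
            root = self._tok(sent, _FILLERS[rng.integers(len(_FILLERS))],
                             "VBD", "O", "O", None, "ROOT")
            self._entity_np(sent, root, "nsubj")
            self._pad(sent, root, 3)
            return

        etype = cfg.event_types[rng.integers(len(cfg.event_types))]
        nominal = rng.random() < 0.5
        trig = self._tok(
            sent, self._trigger_word(etype),
            "NN" if nominal else "VBZ", "O", "B-NP" if nominal else "B-VP",
            None, "ROOT",
        )
        self.layer.triggers.append(EventTrigger(trig, etype))

        # cross-link bookkeeping (only meaningful past the first sentence)
        cross = sent > 0 and bool(earlier) and rng.random() < cfg.cross_link_rate
        zero = cross and rng.random() < cfg.zero_anaphora_fraction
        chained_cross = cross and not zero and cfg.coref_chain_rate > 0

        # one distractor entity, emitted BEFORE the arguments so that
        # neither token position nor attachment distinguishes it from an
        # anaphoric argument: it draws uniformly from the two ambiguous
        # labels used by anaphoric Themes ("nmod") and Causes ("nmod:agt"),
        # so attachment signals a role *type* but never argument-hood
        self._entity_np(sent, trig, "nmod" if rng.random() < 0.5 else "nmod:agt")

        # appositive chain: a mention coreferent with earlier-sentence
        # material that is NOT an argument of anything, so coreference
        # alone never implies a role
        if earlier and rng.random() < cfg.distractor_chain_rate:
            ant = earlier[rng.integers(len(earlier))]
            appos = self._entity_np(sent, trig, "appos", word=ant.word)
            self.layer.corefs.append(CoreferenceLink(appos, ant.head))

        # mandatory Theme, possibly anaphoric.  Anaphoric Themes attach
        # with the ambiguous "nmod" label shared with distractor entities:
        # locally they are indistinguishable from non-arguments, the way a
        # bare anaphoric NP gives no syntactic clue that it is an argument.
        theme_word = None
        antecedent_head = None
        if chained_cross:
            ant = earlier[rng.integers(len(earlier))]
            antecedent_head = ant.head
            theme_word = ant.word
        elif rng.random() < cfg.coref_chain_rate:
            # same-sentence chain: emit the antecedent NP first so it
            # precedes the anaphoric Theme (pure W-ANT structure)
            antecedent_head = self._entity_np(sent, trig, "nmod")
            theme_word = self.tokens[antecedent_head].word
        theme_dep = "obj" if antecedent_head is None else "nmod"
        theme = self._entity_np(sent, trig, theme_dep, word=theme_word)
        self.layer.roles.append(RoleLink(trig, theme, "Theme"))
        if antecedent_head is not None:
            self.layer.corefs.append(CoreferenceLink(theme, antecedent_head))

        # optional Cause, possibly anaphoric.  Unlike the Theme, no global
        # constraint ever forces a Cause, so anaphoric Causes are the part
        # of the corpus only discourse salience can recover.
        if rng.random() < cfg.cause_rate:
            cause_word = None
            cause_ant = None
            if rng.random() < cfg.coref_chain_rate:
                cause_ant = self._entity_np(sent, trig, "nmod:agt")
                cause_word = self.tokens[cause_ant].word
            cause_dep = "nsubj" if cause_ant is None else "nmod:agt"
            cause = self._entity_np(sent, trig, cause_dep, word=cause_word)
            self.layer.roles.append(RoleLink(trig, cause, "Cause"))
            if cause_ant is not None:
                self.layer.corefs.append(CoreferenceLink(cause, cause_ant))

        # zero-anaphora cross link: direct, no chain to explain it
        if zero:
            target = earlier[rng.integers(len(earlier))]
            link = RoleLink(trig, target.head, "Theme")
            if link not in self.layer.roles:
                self.layer.roles.append(link)

        self._pad(sent, trig, None)

    def _pad(self, sent: int, root: int, n: int | None) -> None:
        cfg, rng = self.cfg, self.rng
        if n is None:
            lo, hi = cfg.tokens_per_sentence
            target = int(rng.integers(lo, hi + 1))
            current = sum(1 for t in self.tokens if t.sentence_index == sent)
            n = max(0, target - current)
        for _ in range(n):
            self._tok(sent, _FILLERS[rng.integers(len(_FILLERS))],
                      "IN", "O", "O", root, "mod")

    def finish(self) -> Document:
        # close gold role links over coreference clusters: an argument's role
        # holds for every cluster mate (this is what creates chained
        # cross-links from the chains emitted above)
        from .pipeline import propagate_transitivity
        from .corpus import coref_closure

        clusters = coref_closure(self.layer.corefs)
        self.layer.roles = sorted(propagate_transitivity(self.layer.roles, clusters))
        doc = Document(self.doc_id, self.tokens, gold=self.layer)
        doc.validate()
        return doc


def generate(config: SyntheticConfig) -> list[Document]:
    """Generate a corpus; byte-identical output for a fixed config and seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    docs = []
    for d in range(config.n_docs):
        builder = _DocBuilder(config, rng, f"synth{d:04d}")
        lo, hi = config.sentences_per_doc
        for s in range(int(rng.integers(lo, hi + 1))):
            builder.build_sentence(s)
        docs.append(builder.finish())
    return docs


def separable_config(**overrides) -> SyntheticConfig:
    """A noise-free configuration whose lexical signal is fully separable."""
    return replace(SyntheticConfig(noise_rate=0.0), **overrides)


# -- coreference degradation -------------------------------------------------


def corrupt_coref(
    gold_links: list[CoreferenceLink],
    candidate_pool: list[CoreferenceLink],
    precision: float,
    recall: float,
    seed: int,
) -> list[CoreferenceLink]:
    """Degrade a gold coreference layer to a target precision/recall.

    Keeps each gold link with probability ``recall`` and injects spurious
    links drawn from ``candidate_pool`` (non-gold pairs) until the kept
    links make up a ``precision`` fraction of the output.
    """
    if not 0 < precision <= 1:
        raise ConfigError("precision must lie in (0, 1]")
    if not 0 <= recall <= 1:
        raise ConfigError("recall must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gold_set = set(gold_links)
    kept = [l for l in gold_links if rng.random() < recall]
    n_spurious = round(len(kept) * (1 - precision) / precision)
    pool = [l for l in candidate_pool if l not in gold_set]
    if n_spurious > len(pool):
        raise ConfigError(
            f"target precision {precision} unreachable: needs {n_spurious} "
            f"spurious links but only {len(pool)} candidates exist"
        )
    idx = rng.choice(len(pool), size=n_spurious, replace=False) if n_spurious else []
    return sorted(kept + [pool[int(k)] for k in idx])


def mention_pair_pool(doc: Document, max_sentence_gap: int = 2) -> list[CoreferenceLink]:
    """All orderable NP-head pairs of a document, for spurious-link injection."""
    heads = [
        t.doc_index
        for t in doc.tokens
        if t.chunk.endswith("NP")
        and (t.doc_index + 1 >= len(doc.tokens)
             or not doc.tokens[t.doc_index + 1].chunk.endswith("NP")
             or doc.tokens[t.doc_index + 1].chunk.startswith("B"))
    ]
    out = []
    for a in heads:
        for b in heads:
            if b < a and doc.sentence_of(a) - doc.sentence_of(b) <= max_sentence_gap:
                out.append(CoreferenceLink(a, b))
    return out
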