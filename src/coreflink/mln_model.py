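"""The joint event-extraction model in Markov Logic.

Hidden predicates: ``event(i)``, ``eventType(i,t)``, ``role(i,j,r)``.
Observed predicates carry the local features (simple token properties and
link token properties) plus the symmetric ``corefer`` relation.  Formulae:

* local per-feature-weighted templates tying observed features to each
  hidden predicate;
* four HARD consistency constraints — an event has a type, a type implies
  an event, a role implies an event, and every event has at least one
  Theme argument;
* three soft coreference formulae — *Feature Copy* (FC: an anaphor
  inherits its antecedent's features as evidence for playing a role),
  *Salience in Discourse* (SiD: a coreferent token should be the argument
  of some event in its sentence), and *Transitivity* (T: a role held by an
  anaphor extends to its coreference mates).

One inference instance covers one sentence plus the earlier-sentence
antecedents of its tokens, so grounding stays compact; with no coreference
information the candidate set contains no cross-sentence token and the
model structurally cannot predict a cross-link.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import (
    ROLES,
    Document,
    EntityClusters,
    EventTrigger,
    RoleLink,
    candidate_arguments,
    coref_closure,
)
from .features import (
    build_event_dictionary,
    copy_features,
    link_features,
    token_features,
)
from .mln_core import (
    Assignment,
    Atom,
    Factor,
    GroundNetwork,
    WeightVector,
    learn,
    map_infer,
)
from .pipeline import CorefMode, coref_layer

MODEL_FORMAT_VERSION = 1

PRESETS: dict[str, frozenset[str]] = {
    "baseline": frozenset(),
    "fc": frozenset({"fc"}),
    "fc_sid": frozenset({"fc", "sid"}),
    "fc_t": frozenset({"fc", "t"}),
    "full": frozenset({"fc", "sid", "t"}),
}

# POS prefixes of tokens eligible as event triggers / event-event arguments;
# content-word classes only, which keeps grounding compact
TRIGGER_POS_PREFIXES = ("NN", "VB", "JJ")

# which observed predicates feed which local template
_EVENT_PREDS = ("word", "stem", "ne", "pos", "dict")
_ETYPE_PREDS = ("word", "stem", "dict")
_ROLE_ARG_PREDS = ("word", "ne", "pos")
_ROLE_EVT_PREDS = ("word", "stem")
_ROLE_LINK_PREDS = ("dep", "path", "pathNL", "lca")


class SpecError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Enabled formula families; presets name the coreference ablations."""

    event_types: tuple[str, ...]
    coref_formulae: frozenset[str] = frozenset()

    @staticmethod
    def from_preset(name: str, event_types: Sequence[str]) -> "ModelSpec":
        if name not in PRESETS:
            raise SpecError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return ModelSpec(tuple(event_types), PRESETS[name])

    def __post_init__(self):
        unknown = self.coref_formulae - {"fc", "sid", "t"}
        if unknown:
            raise SpecError(f"unknown coreference formulae {sorted(unknown)}")


def is_trigger_candidate(doc: Document, i: int) -> bool:
    return doc.tokens[i].pos.startswith(TRIGGER_POS_PREFIXES)


# -- observed atoms ----------------------------------------------------------


def build_observed_atoms(
    doc: Document,
    clusters: EntityClusters,
    with_fc: bool = False,
    lexicon: frozenset[str] = frozenset(),
    pairs: Iterable[tuple[int, int]] | None = None,
) -> set[Atom]:
    """Ground observed atoms: token features, pair features, corefer atoms.

    ``pairs`` restricts the (expensive) link-feature atoms to the given
    ordered same-sentence pairs; by default all ordered same-sentence pairs
    are covered.
    """
    atoms: set[Atom] = set()
    for i in range(len(doc.tokens)):
        for key, _ in token_features(i, doc, lexicon).items():
            name, _, value = key.partition("=")
            if name == "punc":
                atoms.add(("punc",))
            elif value:
                atoms.add((name, i, value))
            else:
                atoms.add((name, i))
        if with_fc and clusters.is_clustered(i):
            for key, _ in copy_features(i, clusters, doc).items():
                # key looks like "copied:word=IRF-2"
                atoms.add(("copied", i, key.removeprefix("copied:")))
    if pairs is None:
        pairs = [
            (i, j)
            for s in range(doc.n_sentences())
            for i in doc.sentence_span(s)
            for j in doc.sentence_span(s)
            if i != j
        ]
    for i, j in pairs:
        for key, _ in link_features(i, j, doc).items():
            name, _, value = key.partition("=")
            atoms.add((name, i, j, value))
    for a, b in clusters.pairs():
        atoms.add(("corefer", a, b))
    return atoms


# -- grounding ---------------------------------------------------------------


@dataclass
class InferenceInstance:
    """One sentence window: its hidden-atom domain and ground network."""

    doc_id: str
    sentence: int
    network: GroundNetwork
    gold: Assignment


def ground_sentence(
    doc: Document,
    sentence: int,
    spec: ModelSpec,
    clusters: EntityClusters,
    lexicon: frozenset[str],
) -> InferenceInstance:
    span = list(doc.sentence_span(sentence))
    trig_cands = [i for i in span if is_trigger_candidate(doc, i)]
    arg_cands = sorted(
        j
        for j in candidate_arguments(sentence, doc, clusters)
        if doc.tokens[j].ne != "O" or is_trigger_candidate(doc, j)
    )
    in_sentence = set(span)

    hidden: list[Atom] = []
    for i in trig_cands:
        hidden.append(("event", i))
        for t in spec.event_types:
            hidden.append(("eventType", i, t))
    role_atoms: list[Atom] = []
    for i in trig_cands:
        for j in arg_cands:
            if j == i:
                continue
            for r in ROLES:
                role_atoms.append(("role", i, j, r))
    hidden.extend(role_atoms)

    factors: list[Factor] = []

    # local formulae: per-feature weights
    token_feats = {
        i: token_features(i, doc, lexicon) for i in set(trig_cands) | set(arg_cands)
    }
    for i in trig_cands:
        feats = _named(token_feats[i])
        factors.append(Factor(((("event", i), True),), ("bias_event", None)))
        for name, value in feats:
            if name in _EVENT_PREDS:
                factors.append(
                    Factor(((("event", i), True),), ("evt", f"{name}={value}"))
                )
        for t in spec.event_types:
            factors.append(
                Factor(((("eventType", i, t), True),), ("bias_etype", t))
            )
            for name, value in feats:
                if name in _ETYPE_PREDS:
                    factors.append(
                        Factor(
                            ((("eventType", i, t), True),),
                            ("etype", f"{name}={value}|{t}"),
                        )
                    )
    for atom in role_atoms:
        _, i, j, r = atom
        if j in in_sentence:
            factors.append(Factor(((atom, True),), ("bias_role", r)))
            for name, value in _named(token_feats[j]):
                if name in _ROLE_ARG_PREDS:
                    factors.append(Factor(((atom, True),), ("arg", f"{name}={value}|{r}")))
            for name, value in _named(token_feats[i]):
                if name in _ROLE_EVT_PREDS:
                    factors.append(Factor(((atom, True),), ("revt", f"{name}={value}|{r}")))
            for name, value in _named(link_features(i, j, doc)):
                if name in _ROLE_LINK_PREDS:
                    factors.append(
                        Factor(((atom, True),), ("link", f"{name}={value}|{r}"))
                    )
        else:
            # out-of-sentence candidates carry a single shared prior and no
            # lexical evidence: link features are undefined across
            # sentences, so positive evidence for a cross-link can only
            # come from the coreference formulae, while the prior lets the
            # learner keep the Theme-existence constraint from defaulting
            # into zero-cost cross atoms
            factors.append(Factor(((atom, True),), ("xsent", r)))

    # global consistency formulae (HARD)
    for i in trig_cands:
        factors.append(
            Factor(
                ((("event", i), False),)
                + tuple((("eventType", i, t), True) for t in spec.event_types),
                None,
            )
        )
        for t in spec.event_types:
            factors.append(
                Factor(((("eventType", i, t), False), (("event", i), True)), None)
            )
        theme_atoms = tuple(
            (a, True) for a in role_atoms if a[1] == i and a[3] == "Theme"
        )
        factors.append(Factor(((("event", i), False),) + theme_atoms, None))
    for atom in role_atoms:
        factors.append(Factor(((atom, False), (("event", atom[1]), True)), None))

    # coreference formulae (soft)
    role_set = set(role_atoms)
    if "t" in spec.coref_formulae:
        for atom in role_atoms:
            _, i, j, r = atom
            for k in clusters.mates(j):
                target = ("role", i, k, r)
                if target in role_set:
                    factors.append(
                        Factor(((atom, False), (target, True)), ("t", None))
                    )
    if "sid" in spec.coref_formulae:
        # a coreferent mention is salient: it should be the argument of
        # some event of its sentence, in some role — one existential
        # clause per clustered in-sentence token
        for j in arg_cands:
            if j in in_sentence and clusters.is_clustered(j):
                lits = tuple(
                    (("role", i, j, r), True)
                    for i in trig_cands
                    if i != j
                    for r in ROLES
                )
                if lits:
                    factors.append(Factor(lits, ("sid", None)))
    if "fc" in spec.coref_formulae:
        for j in arg_cands:
            # FC is about an anaphor *in this sentence* inheriting its
            # antecedent's evidence; grounding it on out-of-sentence
            # candidates would smuggle local evidence onto cross-link atoms
            if j not in in_sentence or not clusters.is_clustered(j):
                continue
            # FC is the lexical copying formula corefer(j,k) ∧ word(k,+w)
            # ⇒ role(i,j,+r): evidence flows from the antecedent token's
            # own word form.  Near-constant copied properties (POS, NE,
            # determiner children) would collapse FC into a generic
            # is-clustered bias, duplicating what SiD expresses
            # structurally, so they stay out of this template.
            for k in sorted(clusters.mates(j)):
                if k >= j:
                    continue
                f = f"word={doc.tokens[k].word}"
                for i in trig_cands:
                    if i == j:
                        continue
                    for r in ROLES:
                        factors.append(
                            Factor(((("role", i, j, r), True),), ("fc", f))
                        )

    gold = _gold_assignment(doc, hidden)
    network = GroundNetwork(hidden=hidden, factors=factors)
    return InferenceInstance(doc.doc_id, sentence, network, gold)


def _named(feature_vector: dict) -> list[tuple[str, str]]:
    out = []
    for key in feature_vector:
        name, _, value = key.partition("=")
        out.append((name, value))
    return out


def _gold_assignment(doc: Document, hidden: Sequence[Atom]) -> Assignment:
    gold_types = {t.anchor: t.event_type for t in doc.gold.triggers}
    gold_roles = {(r.event_anchor, r.arg_anchor, r.role) for r in doc.gold.roles}
    out: Assignment = {}
    for atom in hidden:
        if atom[0] == "event":
            out[atom] = atom[1] in gold_types
        elif atom[0] == "eventType":
            out[atom] = gold_types.get(atom[1]) == atom[2]
        else:
            out[atom] = atom[1:] in gold_roles
    return out


# -- model -------------------------------------------------------------------


@dataclass
class MLNModel:
    spec: ModelSpec
    weights: WeightVector
    lexicon: frozenset[str]
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"format_version": MODEL_FORMAT_VERSION, "model": self}, fh)

    @staticmethod
    def load(path) -> "MLNModel":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        if blob.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {blob.get('format_version')}")
        return blob["model"]


def ground_documents(
    docs: Sequence[Document],
    spec: ModelSpec,
    coref_mode: CorefMode,
    lexicon: frozenset[str],
) -> list[InferenceInstance]:
    instances = []
    for doc in docs:
        clusters = coref_closure(coref_layer(doc, coref_mode))
        for s in range(doc.n_sentences()):
            instances.append(ground_sentence(doc, s, spec, clusters, lexicon))
    return instances


def train_mln(
    docs: Sequence[Document],
    preset: str = "full",
    coref_mode: CorefMode = "none",
    event_types: Sequence[str] | None = None,
    epochs: int = 3,
    C: float = 0.1,
    seed: int = 0,
) -> MLNModel:
    """Ground every sentence window once and learn weights online."""
    if event_types is None:
        event_types = sorted({t.event_type for d in docs for t in d.gold.triggers})
    spec = ModelSpec.from_preset(preset, event_types)
    if coref_mode == "none" and spec.coref_formulae:
        # without corefer atoms the coreference formulae never ground, which
        # is exactly the NONE ablation; keep the spec as requested
        pass
    lexicon = build_event_dictionary(docs)
    instances = ground_documents(docs, spec, coref_mode, lexicon)
    pairs = [(inst.network, inst.gold) for inst in instances]
    weights = learn(pairs, epochs=epochs, C=C, seed=seed)
    return MLNModel(
        spec=spec,
        weights=weights,
        lexicon=lexicon,
        meta={"preset": preset, "coref_mode": coref_mode, "epochs": epochs,
              "C": C, "seed": seed},
    )


def predict_mln(doc: Document, model: MLNModel, coref_mode: CorefMode = "none") -> None:
    """Jointly decode every sentence window; writes the document's pred layer."""
    clusters = coref_closure(coref_layer(doc, coref_mode))
    triggers: list[EventTrigger] = []
    roles: set[RoleLink] = set()
    for s in range(doc.n_sentences()):
        inst = ground_sentence(doc, s, model.spec, clusters, model.lexicon)
        assignment = map_infer(inst.network, model.weights)
        typed: dict[int, str] = {}
        for atom, value in assignment.items():
            if value and atom[0] == "eventType" and atom[1] not in typed:
                typed[atom[1]] = atom[2]
        for atom, value in assignment.items():
            if value and atom[0] == "event" and atom[1] in typed:
                triggers.append(EventTrigger(atom[1], typed[atom[1]]))
        for atom, value in assignment.items():
            if value and atom[0] == "role":
                roles.add(RoleLink(atom[1], atom[2], atom[3]))
    doc.pred.triggers = sorted(triggers, key=lambda t: t.anchor)
    doc.pred.roles = sorted(roles)
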