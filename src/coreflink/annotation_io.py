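"""Corpus serialization: a JSON-lines dialect and a standoff export.

JSON lines is the canonical on-disk format: one document object per line,
tokens in order (the document-global index is positional), and the gold and
predicted annotation layers as triples of anchors/labels.  The standoff
export mirrors the shared-task style used for biomedical event corpora:
a text file plus `.a1` (trigger/entity T-lines) and `.a2` (event E-lines,
coreference R-lines) with 0-based half-open character offsets over the
reconstructed text (tokens joined by single spaces, sentences by newlines).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

from .corpus import (
    AnnotationLayer,
    CoreferenceLink,
    CorpusError,
    Document,
    EventTrigger,
    RoleLink,
    Token,
)

_TOKEN_FIELDS = ("word", "stem", "pos", "ne", "chunk", "head", "dep_label")


class ParseError(ValueError):
    """Malformed corpus file; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


# -- jsonl ------------------------------------------------------------------


def _layer_to_obj(layer: AnnotationLayer) -> dict:
    return {
        "triggers": [[t.anchor, t.event_type] for t in layer.triggers],
        "roles": [[r.event_anchor, r.arg_anchor, r.role] for r in layer.roles],
        "corefs": [[c.anaphor, c.antecedent] for c in layer.corefs],
    }


def _layer_from_obj(obj: dict) -> AnnotationLayer:
    return AnnotationLayer(
        triggers=[EventTrigger(int(a), str(t)) for a, t in obj.get("triggers", [])],
        roles=[RoleLink(int(e), int(a), str(r)) for e, a, r in obj.get("roles", [])],
        corefs=[CoreferenceLink(int(a), int(b)) for a, b in obj.get("corefs", [])],
    )


def document_to_obj(doc: Document) -> dict:
    return {
        "doc_id": doc.doc_id,
        "tokens": [
            {
                "sent": t.sentence_index,
                "word": t.word,
                "stem": t.stem,
                "pos": t.pos,
                "ne": t.ne,
                "chunk": t.chunk,
                "head": t.head,
                "dep_label": t.dep_label,
            }
            for t in doc.tokens
        ],
        "gold": _layer_to_obj(doc.gold),
        "pred": _layer_to_obj(doc.pred),
    }


def document_from_obj(obj: dict) -> Document:
    tokens = []
    for i, t in enumerate(obj["tokens"]):
        missing = [f for f in _TOKEN_FIELDS if f not in t]
        if missing:
            raise CorpusError(f"token {i} missing field(s) {missing}")
        tokens.append(
            Token(
                doc_index=i,
                sentence_index=int(t["sent"]),
                word=t["word"],
                stem=t["stem"],
                pos=t["pos"],
                ne=t["ne"],
                chunk=t["chunk"],
                head=None if t["head"] is None else int(t["head"]),
                dep_label=t["dep_label"],
            )
        )
    doc = Document(
        doc_id=str(obj["doc_id"]),
        tokens=tokens,
        gold=_layer_from_obj(obj.get("gold", {})),
        pred=_layer_from_obj(obj.get("pred", {})),
    )
    doc.validate()
    return doc


def write_jsonl(docs: Iterable[Document], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(document_to_obj(doc), sort_keys=True))
            fh.write("\n")


def read_jsonl(path) -> list[Document]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(path, line_no, f"invalid JSON: {exc}") from exc
            try:
                docs.append(document_from_obj(obj))
            except (KeyError, CorpusError, TypeError, ValueError) as exc:
                raise ParseError(path, line_no, f"invalid document: {exc}") from exc
    return docs


def iter_jsonl(path) -> Iterator[Document]:
    yield from read_jsonl(path)


# -- standoff export --------------------------------------------------------


def _token_offsets(doc: Document) -> list[tuple[int, int]]:
    """Character offsets of each token in the reconstructed text."""
    offsets = []
    pos = 0
    prev_sent = None
    for tok in doc.tokens:
        if prev_sent is not None:
            pos += 1  # ' ' within a sentence, '\n' between sentences
        start = pos
        pos += len(tok.word)
        offsets.append((start, pos))
        prev_sent = tok.sentence_index
    return offsets


def reconstruct_text(doc: Document) -> str:
    parts: list[str] = []
    for s in range(doc.n_sentences()):
        parts.append(" ".join(doc.tokens[i].word for i in doc.sentence_span(s)))
    return "\n".join(parts)


def write_standoff(doc: Document, directory, layer: str = "gold") -> dict[str, Path]:
    """Export one document as text + T/E/R standoff files.

    `.a1` holds one T-line per annotated anchor token (triggers keep their
    event type; plain argument tokens are typed `Entity`); `.a2` holds one
    E-line per trigger with its Theme/Cause arguments and one R-line per
    coreference link.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ann: AnnotationLayer = getattr(doc, layer)
    offsets = _token_offsets(doc)
    text = reconstruct_text(doc)

    anchors: list[int] = sorted(
        {t.anchor for t in ann.triggers}
        | {r.arg_anchor for r in ann.roles}
        | {c.anaphor for c in ann.corefs}
        | {c.antecedent for c in ann.corefs}
    )
    trig_type = {t.anchor: t.event_type for t in ann.triggers}
    t_id = {a: f"T{k+1}" for k, a in enumerate(anchors)}

    a1_lines = []
    for a in anchors:
        label = trig_type.get(a, "Entity")
        start, end = offsets[a]
        a1_lines.append(f"{t_id[a]}\t{label} {start} {end}\t{doc.tokens[a].word}")

    a2_lines = []
    for k, trig in enumerate(sorted(ann.triggers, key=lambda t: t.anchor)):
        args = sorted(
            (r for r in ann.roles if r.event_anchor == trig.anchor),
            key=lambda r: (r.role, r.arg_anchor),
        )
        parts = [f"{trig.event_type}:{t_id[trig.anchor]}"]
        counts: dict[str, int] = {}
        for r in args:
            counts[r.role] = counts.get(r.role, 0) + 1
            suffix = "" if counts[r.role] == 1 else str(counts[r.role])
            parts.append(f"{r.role}{suffix}:{t_id[r.arg_anchor]}")
        a2_lines.append(f"E{k+1}\t" + " ".join(parts))
    for k, c in enumerate(sorted(ann.corefs)):
        a2_lines.append(
            f"R{k+1}\tCoreference Anaphor:{t_id[c.anaphor]} Antecedent:{t_id[c.antecedent]}"
        )

    paths = {
        "txt": directory / f"{doc.doc_id}.txt",
        "a1": directory / f"{doc.doc_id}.a1",
        "a2": directory / f"{doc.doc_id}.a2",
    }
    paths["txt"].write_text(text + "\n", encoding="utf-8")
    paths["a1"].write_text("".join(l + "\n" for l in a1_lines), encoding="utf-8")
    paths["a2"].write_text("".join(l + "\n" for l in a2_lines), encoding="utf-8")
    return paths


def read_standoff(directory, doc_id: str) -> Document:
    """Rebuild a document from its standoff export.

    Token tags and the dependency layer are not represented in standoff, so
    the returned document carries placeholder tags and a flat parse; anchors
    and labels of the annotation layer round-trip exactly.
    """
    directory = Path(directory)
    text = (directory / f"{doc_id}.txt").read_text(encoding="utf-8").rstrip("\n")
    tokens: list[Token] = []
    start2idx: dict[int, int] = {}
    pos = 0
    for s, sent in enumerate(text.split("\n")):
        for word in sent.split(" "):
            start2idx[pos] = len(tokens)
            tokens.append(
                Token(
                    doc_index=len(tokens),
                    sentence_index=s,
                    word=word,
                    stem=word.lower(),
                    pos="X",
                    ne="O",
                    chunk="O",
                    head=None,
                    dep_label="dep",
                )
            )
            pos += len(word) + 1
    # flat parse: every non-initial token of a sentence hangs off the first
    roots: dict[int, int] = {}
    for tok in tokens:
        if tok.sentence_index not in roots:
            roots[tok.sentence_index] = tok.doc_index
            tok.head, tok.dep_label = None, "ROOT"
        else:
            tok.head, tok.dep_label = roots[tok.sentence_index], "dep"

    anchor_of: dict[str, int] = {}
    layer = AnnotationLayer()
    for line_no, line in enumerate(
        (directory / f"{doc_id}.a1").read_text(encoding="utf-8").splitlines(), 1
    ):
        tid, span, _word = line.split("\t")
        label, start, _end = span.split(" ")
        if int(start) not in start2idx:
            raise ParseError(directory / f"{doc_id}.a1", line_no, "offset off token grid")
        anchor_of[tid] = start2idx[int(start)]
    events: dict[str, tuple[str, int]] = {}
    for line in (directory / f"{doc_id}.a2").read_text(encoding="utf-8").splitlines():
        eid, body = line.split("\t")
        parts = body.split(" ")
        if eid.startswith("E"):
            etype, tid = parts[0].split(":")
            anchor = anchor_of[tid]
            layer.triggers.append(EventTrigger(anchor, etype))
            events[eid] = (etype, anchor)
            for part in parts[1:]:
                role, tid = part.split(":")
                role = role.rstrip("0123456789")
                layer.roles.append(RoleLink(anchor, anchor_of[tid], role))
        else:
            ana = anchor_of[parts[1].split(":")[1]]
            ant = anchor_of[parts[2].split(":")[1]]
            layer.corefs.append(CoreferenceLink(ana, ant))
    doc = Document(doc_id=doc_id, tokens=tokens, gold=layer)
    doc.validate()
    return doc
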