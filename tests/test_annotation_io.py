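import json

import pytest

from coreflink.annotation_io import (
    ParseError,
    read_jsonl,
    read_standoff,
    reconstruct_text,
    write_jsonl,
    write_standoff,
)
from coreflink.synth import SyntheticConfig, generate


def test_jsonl_round_trip_is_byte_identical(tmp_path, small_corpus):
    p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
    write_jsonl(small_corpus, p1)
    docs = read_jsonl(p1)
    write_jsonl(docs, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_jsonl_preserves_annotations(tmp_path, fig_doc):
    p = tmp_path / "fig.jsonl"
    write_jsonl([fig_doc], p)
    (doc,) = read_jsonl(p)
    assert doc.doc_id == fig_doc.doc_id
    assert doc.gold.triggers == fig_doc.gold.triggers
    assert doc.gold.roles == fig_doc.gold.roles
    assert doc.gold.corefs == fig_doc.gold.corefs
    assert [t.word for t in doc.tokens] == [t.word for t in fig_doc.tokens]


def test_jsonl_parse_error_carries_line_number(tmp_path, fig_doc):
    p = tmp_path / "bad.jsonl"
    write_jsonl([fig_doc], p)
    with open(p, "a") as fh:
        fh.write("{not json\n")
    with pytest.raises(ParseError) as exc:
        read_jsonl(p)
    assert exc.value.line_no == 2
    assert "bad.jsonl:2" in str(exc.value)


def test_jsonl_rejects_missing_token_field(tmp_path, fig_doc):
    p = tmp_path / "bad.jsonl"
    write_jsonl([fig_doc], p)
    obj = json.loads(p.read_text())
    del obj["tokens"][0]["pos"]
    p.write_text(json.dumps(obj) + "\n")
    with pytest.raises(ParseError) as exc:
        read_jsonl(p)
    assert exc.value.line_no == 1


def test_jsonl_rejects_invalid_annotation(tmp_path, fig_doc):
    p = tmp_path / "bad.jsonl"
    write_jsonl([fig_doc], p)
    obj = json.loads(p.read_text())
    obj["gold"]["roles"][0][2] = "Agent"  # unknown role
    p.write_text(json.dumps(obj) + "\n")
    with pytest.raises(ParseError):
        read_jsonl(p)


# -- standoff ----------------------------------------------------------------


def test_standoff_offsets_match_text(tmp_path, fig_doc):
    paths = write_standoff(fig_doc, tmp_path)
    text = paths["txt"].read_text().rstrip("\n")
    assert text == reconstruct_text(fig_doc)
    for line in paths["a1"].read_text().splitlines():
        _tid, span, word = line.split("\t")
        _label, start, end = span.split(" ")
        assert text[int(start) : int(end)] == word


def test_standoff_numbers_repeated_roles(tmp_path, fig_doc):
    # trigger 13 has two Themes -> Theme and Theme2 in the E-line
    paths = write_standoff(fig_doc, tmp_path)
    (e_line,) = [l for l in paths["a2"].read_text().splitlines() if l.startswith("E")]
    assert "Theme:" in e_line and "Theme2:" in e_line and "Cause:" in e_line


def test_standoff_round_trips_annotations(tmp_path, fig_doc):
    write_standoff(fig_doc, tmp_path)
    doc = read_standoff(tmp_path, fig_doc.doc_id)
    assert [t.word for t in doc.tokens] == [t.word for t in fig_doc.tokens]
    assert {(t.anchor, t.event_type) for t in doc.gold.triggers} == {
        (t.anchor, t.event_type) for t in fig_doc.gold.triggers
    }
    assert set(doc.gold.roles) == set(fig_doc.gold.roles)
    assert set(doc.gold.corefs) == set(fig_doc.gold.corefs)


def test_standoff_round_trips_generated_corpus(tmp_path):
    for doc in generate(SyntheticConfig(n_docs=3, seed=5)):
        write_standoff(doc, tmp_path)
        back = read_standoff(tmp_path, doc.doc_id)
        assert set(back.gold.roles) == set(doc.gold.roles)
        assert set(back.gold.corefs) == set(doc.gold.corefs)
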