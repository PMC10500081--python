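"""Parsing, tokenization, BIO conversion and round-trips."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lxml import etree

from picopipe.corpus_io import (
    HeadingMap,
    bio_to_spans,
    is_valid_bio,
    normalize_section,
    read_abstract_text,
    read_conll,
    read_pubmed_xml,
    read_standoff_json,
    repair_bio,
    segment_sentences,
    spans_to_bio,
    tokenize,
    write_conll,
    write_standoff_json,
)
from picopipe.types import TITLE_SID, EntityClass, EntitySpan, SectionLabel, Sentence

from _oracles import random_annotated_sentence, random_valid_bio
from conftest import make_sentence


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text,expected", [
    ("86 hospitalized COVID-19 patients",
     ["86", "hospitalized", "COVID-19", "patients"]),
    ("", []),
    ("placebo.", ["placebo", "."]),
    ("(n=42) vs. placebo,", ["(", "n=42", ")", "vs", ".", "placebo", ","]),
    ("double-blind trial.", ["double-blind", "trial", "."]),
])
def test_tokenize_rule(text, expected):
    assert [t.text for t in tokenize(text)] == expected


def test_tokenize_offsets_faithful():
    rng = np.random.default_rng(7)
    texts = ["  Mixed   spacing, here. ", "A (b) c-d 1.5%", ""]
    texts += [" ".join(str(rng.choice(["ab", "c.", "(d)", "e-f", "9%"])
                       ) for _ in range(int(rng.integers(0, 8))))
              for _ in range(50)]
    for text in texts:
        toks = tokenize(text)
        for t in toks:
            assert text[t.start:t.end] == t.text
        # non-overlapping and sorted
        for a, b in zip(toks, toks[1:]):
            assert a.end <= b.start
        # concatenating slices + skipped whitespace reconstructs the text
        rebuilt = []
        cursor = 0
        for t in toks:
            rebuilt.append(text[cursor:t.start])
            rebuilt.append(t.text)
            cursor = t.end
        rebuilt.append(text[cursor:])
        assert "".join(rebuilt) == text
        assert all(not text[a.end:b.start].strip() for a, b in zip(toks, toks[1:]))


def test_segmentation_splits_on_capital_and_protects_abbreviations():
    assert segment_sentences("We did X. We measured Y.") == \
        ["We did X.", "We measured Y."]
    assert segment_sentences("Drug A vs. placebo was tested. Results follow.") == \
        ["Drug A vs. placebo was tested.", "Results follow."]
    assert segment_sentences("") == []


# ---------------------------------------------------------------------------
# Section normalization and heading maps
# ---------------------------------------------------------------------------

def test_normalize_section_contract():
    assert normalize_section("OBJECTIVE") is SectionLabel.BACKGROUND
    assert normalize_section("methods") is SectionLabel.METHODS
    with pytest.raises(ValueError, match="unmappable"):
        normalize_section("design")


def test_normalize_section_idempotent():
    for raw in ["background", "objective", "methods", "results", "conclusions"]:
        once = normalize_section(raw)
        assert normalize_section(once.value) is once


def test_default_heading_map_lookup():
    hm = HeadingMap.default()
    assert len(hm) >= 40
    assert hm.lookup("METHODS:") is SectionLabel.METHODS
    assert hm.lookup("  objectives ") is SectionLabel.BACKGROUND
    assert hm.lookup("NOSUCHHEADING") is None


# ---------------------------------------------------------------------------
# Plain-text reader
# ---------------------------------------------------------------------------

def test_read_abstract_text_title_only():
    ab = read_abstract_text(io.StringIO("Only a title\n"))
    assert ab.title == "Only a title"
    assert ab.sentences == [] and ab.structured is False


def test_read_abstract_text_headings():
    ab = read_abstract_text(io.StringIO("T.\nMETHODS: We did X. We measured Y.\n"))
    assert ab.structured is True
    assert [s.text for s in ab.sentences] == ["We did X.", "We measured Y."]
    assert all(s.gold_section is SectionLabel.METHODS for s in ab.sentences)


def test_read_abstract_text_unknown_heading_warns(caplog):
    with caplog.at_level("WARNING"):
        ab = read_abstract_text(io.StringIO("T.\nFOO: Something happened here.\n"))
    assert ab.structured is False
    assert ab.sentences[0].gold_section is None
    assert any("FOO" in rec.message for rec in caplog.records)


def test_read_abstract_text_empty_is_error(tmp_path):
    with pytest.raises(ValueError, match="empty document"):
        read_abstract_text(io.StringIO("   \n \n"))
    bad = tmp_path / "bad.txt"
    bad.write_bytes(b"Title\nMETHODS: caf\xe9 latin-1 bytes")
    with pytest.raises(ValueError, match="offset"):
        read_abstract_text(bad)


# ---------------------------------------------------------------------------
# PubMed XML reader
# ---------------------------------------------------------------------------

_XML = """<PubmedArticleSet>
 <PubmedArticle>
  <PMID>101</PMID>
  <ArticleTitle>A trial.</ArticleTitle>
  <Abstract>
   <AbstractText Label="METHODS" NlmCategory="METHODS">We did things. We saw results.</AbstractText>
   <AbstractText Label="OBJECTIVE" NlmCategory="OBJECTIVE">Aim was stated.</AbstractText>
  </Abstract>
 </PubmedArticle>
 <PubmedArticle>
  <PMID>102</PMID>
  <ArticleTitle>No abstract here.</ArticleTitle>
 </PubmedArticle>
</PubmedArticleSet>"""


def test_read_pubmed_xml(caplog):
    with caplog.at_level("WARNING"):
        corpus = read_pubmed_xml(io.BytesIO(_XML.encode()))
    assert [ab.doc_id for ab in corpus] == ["101", "102"]
    ab = corpus[0]
    assert ab.structured
    methods = [s for s in ab.sentences if s.gold_section is SectionLabel.METHODS]
    assert len(methods) == 2
    # objective remaps to background
    assert ab.sentences[-1].gold_section is SectionLabel.BACKGROUND
    # record without AbstractText -> empty with warning
    assert corpus[1].sentences == []
    assert any("no AbstractText" in r.message for r in caplog.records)


def test_read_pubmed_xml_malformed_reports_line():
    with pytest.raises(etree.XMLSyntaxError):
        read_pubmed_xml(io.BytesIO(b"<a><ArticleTitle>x</a>"))


# ---------------------------------------------------------------------------
# BIO conversion
# ---------------------------------------------------------------------------

def test_spans_to_bio_definition():
    sent = make_sentence("alpha beta gamma delta")
    span = EntitySpan(sid=0, start=0, end=10, cls=EntityClass.P, text="alpha beta")
    assert spans_to_bio(sent, [span]) == ["B-P", "I-P", "O", "O"]
    assert spans_to_bio(sent, []) == ["O"] * 4


def test_spans_to_bio_adjacent_spans():
    sent = make_sentence("alpha beta gamma")
    s1 = EntitySpan(sid=0, start=0, end=5, cls=EntityClass.I, text="alpha")
    s2 = EntitySpan(sid=0, start=6, end=10, cls=EntityClass.C, text="beta")
    assert spans_to_bio(sent, [s1, s2]) == ["B-I", "B-C", "O"]


def test_spans_to_bio_rejects_misaligned_and_overlapping():
    sent = make_sentence("alpha beta")
    mis = EntitySpan(sid=0, start=0, end=3, cls=EntityClass.P, text="alp")
    with pytest.raises(ValueError, match="alp"):
        spans_to_bio(sent, [mis])
    a = EntitySpan(sid=0, start=0, end=10, cls=EntityClass.P, text="alpha beta")
    b = EntitySpan(sid=0, start=6, end=10, cls=EntityClass.I, text="beta")
    with pytest.raises(ValueError, match="overlap"):
        spans_to_bio(sent, [a, b])


def test_bio_to_spans_repair_policy():
    sent = make_sentence("alpha beta gamma")
    spans = bio_to_spans(sent, ["O", "I-P", "O"])
    assert len(spans) == 1
    sp = spans[0]
    assert (sp.start, sp.end, sp.cls) == (6, 10, EntityClass.P)
    assert bio_to_spans(sent, ["O", "O", "O"]) == []
    with pytest.raises(ValueError, match="length"):
        bio_to_spans(sent, ["O", "O"])


def test_repair_preserves_valid_sequences():
    rng = np.random.default_rng(5)
    for _ in range(200):
        tags = random_valid_bio(rng, int(rng.integers(0, 12)))
        assert is_valid_bio(tags)
        assert repair_bio(tags) == tags


def test_bio_round_trip_random():
    """spans -> BIO -> spans is the identity on random valid annotations."""
    rng = np.random.default_rng(123)
    for _ in range(1000):
        sent, spans = random_annotated_sentence(rng)
        tags = spans_to_bio(sent, spans)
        assert is_valid_bio(tags)
        assert bio_to_spans(sent, tags) == sorted(spans)


@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=200, derandomize=True, deadline=None)
def test_bio_round_trip_property(seed):
    """Round-trip identity as a hypothesis property over generator seeds."""
    sent, spans = random_annotated_sentence(np.random.default_rng(seed))
    assert bio_to_spans(sent, spans_to_bio(sent, spans)) == sorted(spans)


# ---------------------------------------------------------------------------
# CoNLL and JSON round-trips
# ---------------------------------------------------------------------------

def _tags_by_sentence(corpus):
    out = []
    for ab in corpus:
        by_sid = {}
        for sp in ab.entities:
            by_sid.setdefault(sp.sid, []).append(sp)
        for sent in ab.all_sentences():
            out.append((
                ab.doc_id, sent.sid,
                sent.gold_section.value if sent.gold_section else None,
                [t.text for t in sent.tokens],
                spans_to_bio(sent, by_sid.get(sent.sid, [])),
            ))
    return out


def test_conll_round_trip(separable_corpus, tmp_path):
    corpus = separable_corpus[:3]
    path = tmp_path / "c.conll"
    write_conll(corpus, path)
    back = read_conll(path)
    assert _tags_by_sentence(back) == _tags_by_sentence(corpus)


def test_conll_ragged_line_rejected(tmp_path):
    path = tmp_path / "bad.conll"
    path.write_text("-DOCSTART- d 0 methods\nalpha\tO\textra\n")
    with pytest.raises(ValueError, match="line 2"):
        read_conll(path)


def test_conll_empty_file(tmp_path):
    path = tmp_path / "empty.conll"
    path.write_text("")
    assert read_conll(path) == []


def test_standoff_json_round_trip(separable_corpus, tmp_path):
    corpus = separable_corpus[:3]
    path = tmp_path / "c.json"
    write_standoff_json(corpus, path)
    back = read_standoff_json(path)
    assert len(back) == len(corpus)
    for a, b in zip(corpus, back):
        assert a.doc_id == b.doc_id and a.title == b.title
        assert [s.text for s in a.sentences] == [s.text for s in b.sentences]
        assert sorted(a.entities) == sorted(b.entities)


def test_standoff_json_rejects_text_mismatch(tmp_path):
    payload = """[{"doc_id": "d", "title": "T", "structured": false,
      "sentences": [{"sid": 0, "text": "alpha beta", "gold_section": null,
                     "pred_section": null}],
      "entities": [{"sid": 0, "start": 0, "end": 5, "cls": "P", "text": "beta"}],
      "pred_entities": []}]"""
    path = tmp_path / "bad.json"
    path.write_text(payload)
    with pytest.raises(ValueError, match="d"):
        read_standoff_json(path)


def test_standoff_json_empty(tmp_path):
    path = tmp_path / "empty.json"
    path.write_text("[]")
    assert read_standoff_json(path) == []
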