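"""Reading, writing and converting abstracts, annotations and tag files.

Supported dialects
------------------
* MEDLINE-style plain text: a title line followed by optional
  ``HEADING: text`` lines (:func:`read_abstract_text`).
* A minimal PubMed-XML subset: ``ArticleTitle`` plus ``AbstractText``
  elements with optional ``NlmCategory``/``Label`` attributes
  (:func:`read_pubmed_xml`).
* CoNLL-style token/tag files, one token per line (:func:`read_conll` /
  :func:`write_conll`).
* JSON standoff with character-offset spans (:func:`read_standoff_json` /
  :func:`write_standoff_json`).

All character offsets are 0-based and half-open.  Tokenization is a
deterministic rule: split on whitespace, then peel leading/trailing
punctuation into separate tokens, keeping internal hyphens and digits
intact (so ``COVID-19`` stays one token while ``placebo.`` becomes two).
"""

from __future__ import annotations

import io
import json
import logging
import re
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Optional, Union

from lxml import etree

from .types import (
    TITLE_SID,
    Abstract,
    Corpus,
    EntityClass,
    EntitySpan,
    SectionLabel,
    Sentence,
    Token,
)

logger = logging.getLogger(__name__)

PathOrStream = Union[str, Path, IO[str]]

# ---------------------------------------------------------------------------
# Tokenization and sentence segmentation
# ---------------------------------------------------------------------------

#: Punctuation peeled off token edges.  Hyphens are deliberately absent so
#: hyphenated terms ("COVID-19", "double-blind") survive as single tokens.
_EDGE_PUNCT = set(".,;:!?()[]{}\"'%‘’“”")


def tokenize(text: str) -> list[Token]:
    """Deterministic offset-faithful tokenization of one sentence."""
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text):
        s, e = m.start(), m.end()
        # leading punctuation
        while s < e and text[s] in _EDGE_PUNCT:
            tokens.append(Token(text[s], s, s + 1))
            s += 1
        # trailing punctuation (collected, then emitted in order)
        trailing: list[Token] = []
        while e - 1 >= s and text[e - 1] in _EDGE_PUNCT:
            trailing.append(Token(text[e - 1], e - 1, e))
            e -= 1
        if s < e:
            tokens.append(Token(text[s:e], s, e))
        tokens.extend(reversed(trailing))
    return tokens


#: Abbreviations that do not end a sentence even when followed by a capital.
_ABBREVIATIONS = {
    "vs", "e.g", "i.e", "etc", "dr", "mr", "mrs", "ms", "prof", "fig",
    "al", "st", "no", "ca", "approx", "cf",
}

_BOUNDARY = re.compile(r"[.?!]+(?=\s+[\"'(]?[A-Z0-9])")


def segment_sentences(text: str) -> list[str]:
    """Rule-based sentence splitting.

    Splits after ``.?!`` when followed by whitespace and a capital letter or
    digit, unless the preceding word is a known abbreviation or a single
    initial.  Deterministic and total.
    """
    text = text.strip()
    if not text:
        return []
    pieces: list[str] = []
    last = 0
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        before = text[last : m.start()]
        word = before.rsplit(None, 1)[-1] if before.split() else ""
        word = word.rstrip(".").lstrip("(\"'").lower()
        if word in _ABBREVIATIONS:
            continue
        pieces.append(text[last:end].strip())
        last = end
    tail = text[last:].strip()
    if tail:
        pieces.append(tail)
    return [p for p in pieces if p]


# ---------------------------------------------------------------------------
# Section-label normalization and heading maps
# ---------------------------------------------------------------------------

#: Raw categories accepted from heading maps / NlmCategory attributes.
_RAW_CATEGORIES = {
    "background": SectionLabel.BACKGROUND,
    # Background and objective sentences are hard to tell apart, so the
    # objective category is folded into background throughout.
    "objective": SectionLabel.BACKGROUND,
    "methods": SectionLabel.METHODS,
    "results": SectionLabel.RESULTS,
    "conclusions": SectionLabel.CONCLUSIONS,
}


def normalize_section(raw: str) -> SectionLabel:
    """Map a raw category to its canonical section label.

    ``objective`` maps to ``background``; the other four categories map to
    themselves.  Idempotent: feeding a canonical label back in returns it.
    """
    key = raw.strip().lower()
    if key not in _RAW_CATEGORIES:
        raise ValueError(f"unmappable category: {raw!r}")
    return _RAW_CATEGORIES[key]


class HeadingMap:
    """Case-insensitive map from abstract heading strings to raw categories.

    Mirrors the NLM structured-abstract label/category mapping: many
    concrete headings (``PATIENTS AND METHODS``, ``MAIN OUTCOME MEASURES``,
    ...) collapse onto the five raw categories.  Lookups normalize the
    heading (uppercase, strip trailing colon and whitespace); unknown
    headings return ``None`` and are the caller's job to report.
    """

    def __init__(self, rows: dict[str, str]):
        self._rows: dict[str, str] = {}
        for heading, category in rows.items():
            if category.strip().lower() not in _RAW_CATEGORIES:
                raise ValueError(
                    f"heading {heading!r} maps to unknown category {category!r}"
                )
            self._rows[self._norm(heading)] = category.strip().lower()

    @staticmethod
    def _norm(heading: str) -> str:
        return heading.strip().rstrip(":").strip().upper()

    def lookup(self, heading: str) -> Optional[SectionLabel]:
        raw = self._rows.get(self._norm(heading))
        return normalize_section(raw) if raw is not None else None

    def __contains__(self, heading: str) -> bool:
        return self._norm(heading) in self._rows

    def __len__(self) -> int:
        return len(self._rows)

    @classmethod
    def from_tsv(cls, source: PathOrStream) -> "HeadingMap":
        """Load a two-column TSV (heading <TAB> category)."""
        close = False
        if isinstance(source, (str, Path)):
            fh: IO[str] = open(source, "r", encoding="utf-8")
            close = True
        else:
            fh = source
        try:
            rows: dict[str, str] = {}
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"line {lineno}: expected 2 columns, got {len(parts)}")
                rows[parts[0]] = parts[1]
            return cls(rows)
        finally:
            if close:
                fh.close()

    @classmethod
    def default(cls) -> "HeadingMap":
        """The packaged map of common structured-abstract headings."""
        text = resources.files("picopipe.data").joinpath("heading_map.tsv").read_text()
        return cls.from_tsv(io.StringIO(text))


# ---------------------------------------------------------------------------
# Plain-text (MEDLINE-style) reader
# ---------------------------------------------------------------------------

_HEADING_LINE = re.compile(r"^\s*([A-Za-z][A-Za-z0-9 /&,\-]{0,60}?)\s*:\s*(.*)$")


def _read_text_source(source: PathOrStream) -> str:
    if isinstance(source, (str, Path)):
        data = Path(source).read_bytes()
        try:
            return data.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise ValueError(
                f"undecodable bytes at offset {exc.start} in {source}"
            ) from exc
    return source.read()


def read_abstract_text(
    source: PathOrStream,
    heading_map: Optional[HeadingMap] = None,
    doc_id: str = "doc",
) -> Abstract:
    """Parse a MEDLINE-style plain-text abstract.

    The first non-empty line is the title.  Subsequent lines may start with
    ``HEADING:``; headings found in the map label their sentences, unknown
    headings are logged and leave sentences unlabeled, and heading-less
    lines inherit the currently open section.  ``structured`` is true iff
    at least one heading matched the map.
    """
    if heading_map is None:
        heading_map = HeadingMap.default()
    text = _read_text_source(source)
    lines = [ln for ln in text.splitlines()]
    # title = first non-empty line
    title = ""
    body_start = 0
    for i, ln in enumerate(lines):
        if ln.strip():
            title = ln.strip()
            body_start = i + 1
            break
    if not title:
        raise ValueError("empty document")

    sentences: list[Sentence] = []
    structured = False
    current: Optional[SectionLabel] = None
    for ln in lines[body_start:]:
        if not ln.strip():
            continue
        content = ln.strip()
        m = _HEADING_LINE.match(content)
        if m and m.group(1).strip().upper() == m.group(1).strip():
            heading, rest = m.group(1), m.group(2)
            label = heading_map.lookup(heading)
            if label is not None:
                structured = True
                current = label
            else:
                logger.warning("unknown heading %r in %s; sentences left unlabeled",
                               heading, doc_id)
                current = None
            content = rest
        for piece in segment_sentences(content):
            sentences.append(
                Sentence(
                    sid=len(sentences),
                    text=piece,
                    tokens=tokenize(piece),
                    gold_section=current,
                )
            )
    return Abstract(doc_id=doc_id, title=title, sentences=sentences,
                    structured=structured)


# ---------------------------------------------------------------------------
# PubMed-XML subset reader
# ---------------------------------------------------------------------------


def read_pubmed_xml(source: PathOrStream) -> Corpus:
    """Parse a minimal PubMed-XML subset into a corpus.

    Recognizes ``ArticleTitle`` and ``AbstractText`` elements; a
    ``NlmCategory`` (or, failing that, ``Label``) attribute labels the
    element's sentences after normalization.  Records without any
    ``AbstractText`` yield an abstract with no sentences and a warning.
    Malformed XML raises ``lxml``'s parse error, which carries the line
    number.
    """
    if isinstance(source, (str, Path)):
        tree = etree.parse(str(source))
    else:
        tree = etree.parse(source)
    root = tree.getroot()

    records = root.findall(".//PubmedArticle")
    if not records:
        records = [root] if root.find(".//ArticleTitle") is not None else []

    corpus: Corpus = []
    for i, rec in enumerate(records):
        pmid_el = rec.find(".//PMID")
        doc_id = pmid_el.text.strip() if pmid_el is not None and pmid_el.text else f"xml-{i}"
        title_el = rec.find(".//ArticleTitle")
        title = (title_el.text or "").strip() if title_el is not None else ""
        if not title:
            raise ValueError(f"record {doc_id}: missing ArticleTitle")

        abstract_els = rec.findall(".//AbstractText")
        if not abstract_els:
            logger.warning("record %s has no AbstractText; empty abstract", doc_id)

        sentences: list[Sentence] = []
        structured = False
        for el in abstract_els:
            raw = el.get("NlmCategory") or el.get("Label")
            label: Optional[SectionLabel] = None
            if raw:
                try:
                    label = normalize_section(raw)
                    structured = True
                except ValueError:
                    logger.warning("record %s: unmappable category %r", doc_id, raw)
            for piece in segment_sentences(el.text or ""):
                sentences.append(
                    Sentence(
                        sid=len(sentences),
                        text=piece,
                        tokens=tokenize(piece),
                        gold_section=label,
                    )
                )
        corpus.append(Abstract(doc_id=doc_id, title=title, sentences=sentences,
                               structured=structured))
    return corpus


# ---------------------------------------------------------------------------
# BIO tag sequences
# ---------------------------------------------------------------------------

#: Full BIO label inventory: Outside + Begin/Inside for each PICO class,
#: in decoder tie-break order (O first, then lexicographic).
BIO_LABELS: tuple[str, ...] = (
    "O",
    "B-C", "B-I", "B-O", "B-P",
    "I-C", "I-I", "I-O", "I-P",
)


def is_valid_bio(tags: Iterable[str]) -> bool:
    """True iff no I-c follows O, start, or a different class."""
    prev = "O"
    for tag in tags:
        if tag.startswith("I-"):
            cls = tag[2:]
            if prev == "O" or prev[2:] != cls:
                return False
        prev = tag
    return True


def repair_bio(tags: list[str]) -> list[str]:
    """Conservative-begin repair: a stranded I-c becomes B-c.

    Preserves the predicted extent of every entity; needed only for
    backends that predict token labels independently.
    """
    out: list[str] = []
    prev = "O"
    for tag in tags:
        if tag.startswith("I-") and (prev == "O" or prev[2:] != tag[2:]):
            tag = "B-" + tag[2:]
        out.append(tag)
        prev = tag
    return out


def spans_to_bio(sentence: Sentence, spans: Iterable[EntitySpan]) -> list[str]:
    """Project token-aligned entity spans onto a BIO tag sequence."""
    spans = sorted(spans)
    starts = {t.start: i for i, t in enumerate(sentence.tokens)}
    ends = {t.end: i for i, t in enumerate(sentence.tokens)}
    tags = ["O"] * len(sentence.tokens)
    prev_end = -1
    for span in spans:
        if span.sid != sentence.sid:
            raise ValueError(f"span {span} does not belong to sentence {sentence.sid}")
        if span.start < prev_end:
            raise ValueError(f"overlapping span {span}")
        if span.start not in starts or span.end not in ends:
            raise ValueError(
                f"span {span.text!r} [{span.start},{span.end}) is not aligned with "
                f"token boundaries of sentence {sentence.sid}"
            )
        first, last = starts[span.start], ends[span.end]
        tags[first] = f"B-{span.cls.value}"
        for i in range(first + 1, last + 1):
            tags[i] = f"I-{span.cls.value}"
        prev_end = span.end
    return tags


def bio_to_spans(sentence: Sentence, tags: list[str]) -> list[EntitySpan]:
    """Reconstruct entity spans from a BIO sequence (repairing if invalid)."""
    if len(tags) != len(sentence.tokens):
        raise ValueError(
            f"tag sequence length {len(tags)} != token count "
            f"{len(sentence.tokens)} (sid={sentence.sid})"
        )
    tags = repair_bio(list(tags))
    spans: list[EntitySpan] = []
    open_cls: Optional[str] = None
    open_first = 0
    for i, tag in enumerate(tags + ["O"]):  # sentinel flushes the last span
        if open_cls is not None and (tag == "O" or tag.startswith("B-")
                                     or i == len(tags)):
            start = sentence.tokens[open_first].start
            end = sentence.tokens[i - 1].end
            spans.append(EntitySpan(sid=sentence.sid, start=start, end=end,
                                    cls=EntityClass(open_cls),
                                    text=sentence.text[start:end]))
            open_cls = None
        if i < len(tags) and tag.startswith("B-"):
            open_cls = tag[2:]
            open_first = i
    return spans


# ---------------------------------------------------------------------------
# CoNLL reader/writer
# ---------------------------------------------------------------------------

_DOCSTART = "-DOCSTART-"


def write_conll(corpus: Corpus, path: PathOrStream, tags_from: str = "gold") -> None:
    """Write token/tag lines, one sentence block per sentence.

    Block header: ``-DOCSTART- <doc_id> <sid> <section>``; then one
    ``token<TAB>tag`` line per token and a blank line.  Whitespace between
    tokens is not preserved (sentences re-join with single spaces on read).
    """
    close = False
    if isinstance(path, (str, Path)):
        fh: IO[str] = open(path, "w", encoding="utf-8")
        close = True
    else:
        fh = path
    try:
        for ab in corpus:
            span_source = ab.entities if tags_from == "gold" else ab.pred_entities
            by_sid: dict[int, list[EntitySpan]] = {}
            for span in span_source:
                by_sid.setdefault(span.sid, []).append(span)
            for sent in ab.all_sentences():
                section = sent.gold_section.value if sent.gold_section else "-"
                fh.write(f"{_DOCSTART} {ab.doc_id} {sent.sid} {section}\n")
                tags = spans_to_bio(sent, by_sid.get(sent.sid, []))
                for tok, tag in zip(sent.tokens, tags):
                    fh.write(f"{tok.text}\t{tag}\n")
                fh.write("\n")
    finally:
        if close:
            fh.close()


def read_conll(path: PathOrStream) -> Corpus:
    """Inverse of :func:`write_conll` on tokens, tags and section labels."""
    close = False
    if isinstance(path, (str, Path)):
        fh: IO[str] = open(path, "r", encoding="utf-8")
        close = True
    else:
        fh = path
    try:
        docs: dict[str, Abstract] = {}
        order: list[str] = []
        block_header: Optional[tuple[str, int, str]] = None
        block_tokens: list[tuple[str, str]] = []

        def flush() -> None:
            nonlocal block_header, block_tokens
            if block_header is None:
                return
            doc_id, sid, section = block_header
            words = [w for w, _ in block_tokens]
            text = " ".join(words)
            sent = Sentence(
                sid=sid,
                text=text,
                tokens=tokenize(text),
                gold_section=SectionLabel(section) if section != "-" else None,
            )
            if len(sent.tokens) != len(block_tokens):
                # joined text must re-tokenize to the same tokens
                raise ValueError(
                    f"sentence {sid} of {doc_id} does not round-trip through "
                    "tokenization"
                )
            if doc_id not in docs:
                docs[doc_id] = Abstract(doc_id=doc_id, title="")
                order.append(doc_id)
            ab = docs[doc_id]
            spans = bio_to_spans(sent, [t for _, t in block_tokens])
            if sid == TITLE_SID:
                ab.title = text
                ab.entities.extend(spans)
            else:
                ab.sentences.append(sent)
                ab.entities.extend(spans)
            block_header = None
            block_tokens = []

        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith(_DOCSTART):
                flush()
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(f"line {lineno}: malformed block header")
                block_header = (parts[1], int(parts[2]), parts[3])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"line {lineno}: expected 'token<TAB>tag', got {len(parts)} fields"
                )
            if block_header is None:
                raise ValueError(f"line {lineno}: token line outside a sentence block")
            block_tokens.append((parts[0], parts[1]))
        flush()
        corpus = [docs[d] for d in order]
        for ab in corpus:
            ab.sentences.sort(key=lambda s: s.sid)
            ab.validate()
        return corpus
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# JSON standoff reader/writer
# ---------------------------------------------------------------------------


def _span_to_dict(span: EntitySpan) -> dict:
    return {"sid": span.sid, "start": span.start, "end": span.end,
            "cls": span.cls.value, "text": span.text}


def _span_from_dict(d: dict) -> EntitySpan:
    return EntitySpan(sid=d["sid"], start=d["start"], end=d["end"],
                      cls=EntityClass(d["cls"]), text=d["text"])


def write_standoff_json(corpus: Corpus, path: PathOrStream) -> None:
    """Serialize a corpus (sentences, sections, gold + predicted spans)."""
    payload = []
    for ab in corpus:
        payload.append({
            "doc_id": ab.doc_id,
            "title": ab.title,
            "structured": ab.structured,
            "sentences": [
                {
                    "sid": s.sid,
                    "text": s.text,
                    "gold_section": s.gold_section.value if s.gold_section else None,
                    "pred_section": s.pred_section.value if s.pred_section else None,
                }
                for s in ab.sentences
            ],
            "entities": [_span_to_dict(sp) for sp in sorted(ab.entities)],
            "pred_entities": [_span_to_dict(sp) for sp in sorted(ab.pred_entities)],
        })
    if isinstance(path, (str, Path)):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    else:
        json.dump(payload, path, indent=1)


def read_standoff_json(path: PathOrStream) -> Corpus:
    """Load standoff JSON, re-validating every span against sentence text."""
    if isinstance(path, (str, Path)):
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    else:
        payload = json.load(path)
    corpus: Corpus = []
    for d in payload:
        sentences = [
            Sentence(
                sid=s["sid"],
                text=s["text"],
                tokens=tokenize(s["text"]),
                gold_section=SectionLabel(s["gold_section"]) if s.get("gold_section") else None,
                pred_section=SectionLabel(s["pred_section"]) if s.get("pred_section") else None,
            )
            for s in d["sentences"]
        ]
        ab = Abstract(
            doc_id=d["doc_id"],
            title=d["title"],
            sentences=sentences,
            entities=[_span_from_dict(sp) for sp in d.get("entities", [])],
            structured=d.get("structured", False),
            pred_entities=[_span_from_dict(sp) for sp in d.get("pred_entities", [])],
        )
        try:
            ab.validate()
        except ValueError as exc:
            raise ValueError(f"invalid standoff record {ab.doc_id}: {exc}") from exc
        corpus.append(ab)
    return corpus
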