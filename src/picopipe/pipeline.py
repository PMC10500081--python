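"""Two-step extraction pipeline: classify sections, filter, tag, aggregate.

The pipeline mirrors how PICO information is distributed in trial
abstracts: the title and methods section carry nearly all unique PICO
mentions, so sentences are first assigned a rhetorical section, then only
the title and the methods-labeled sentences are passed to the tagger.
Per-document unique mentions are finally aggregated into
:class:`PicoRecord` objects (case-insensitive exact-string deduplication
within each class; merging lexical variants or abbreviations is out of
scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .pico_tagger import TaggerModel, tag_corpus
from .section_classifier import ClassifierModel, classify_abstract
from .types import (
    ENTITY_CLASSES,
    Abstract,
    Corpus,
    EntityClass,
    EntitySpan,
    SectionLabel,
    Sentence,
)

DEFAULT_SECTIONS_TO_TAG = frozenset({SectionLabel.TITLE, SectionLabel.METHODS})


def normalize_mention(text: str) -> str:
    """Dedup key: casefold + whitespace collapse (exact match within class)."""
    return " ".join(text.casefold().split())


@dataclass
class PicoMention:
    text: str  # normalized surface form
    spans: list[EntitySpan]


@dataclass
class PicoRecord:
    """Unique PICO elements retrieved from one abstract."""

    doc_id: str
    elements: dict[EntityClass, list[PicoMention]] = field(default_factory=dict)

    def unique_strings(self, cls: EntityClass) -> list[str]:
        return [m.text for m in self.elements.get(cls, [])]

    def validate(self) -> None:
        for cls, mentions in self.elements.items():
            texts = [m.text for m in mentions]
            if len(texts) != len(set(texts)):
                raise ValueError(f"{self.doc_id}: duplicate {cls} mention strings")
            for m in mentions:
                if not m.spans:
                    raise ValueError(
                        f"{self.doc_id}: mention {m.text!r} has no source span"
                    )

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "elements": {
                cls.value: [
                    {"text": m.text,
                     "spans": [{"sid": s.sid, "start": s.start, "end": s.end,
                                "text": s.text} for s in m.spans]}
                    for m in self.elements.get(cls, [])
                ]
                for cls in ENTITY_CLASSES
            },
        }


def build_pico_record(abstract: Abstract, spans: Optional[Iterable[EntitySpan]] = None
                      ) -> PicoRecord:
    """Aggregate spans (default: predicted) into unique per-class mentions."""
    if spans is None:
        spans = abstract.pred_entities
    record = PicoRecord(doc_id=abstract.doc_id)
    index: dict[EntityClass, dict[str, PicoMention]] = {}
    for span in sorted(spans):
        key = normalize_mention(span.text)
        bucket = index.setdefault(span.cls, {})
        if key not in bucket:
            mention = PicoMention(text=key, spans=[])
            bucket[key] = mention
            record.elements.setdefault(span.cls, []).append(mention)
        bucket[key].spans.append(span)
    record.validate()
    return record


@dataclass
class PipelineConfig:
    """Configuration of the two-step system."""

    classifier: ClassifierModel
    tagger: TaggerModel
    sections_to_tag: frozenset[SectionLabel] = DEFAULT_SECTIONS_TO_TAG
    trust_headings: bool = False
    monotone_sections: bool = False


def filter_sentences(abstract: Abstract,
                     sections_to_tag: Iterable[SectionLabel] = DEFAULT_SECTIONS_TO_TAG,
                     use_sections: str = "pred") -> list[Sentence]:
    """Title pseudo-sentence plus body sentences in the selected sections.

    The title is always included (it is annotated structurally); body
    order is preserved.
    """
    wanted = set(sections_to_tag)
    out = [abstract.title_sentence]
    for sent in abstract.sentences:
        sec = sent.effective_section(prefer=use_sections)
        if sec is not None and sec in wanted:
            out.append(sent)
    return out


def run_pipeline(config: PipelineConfig, abstracts: Corpus
                 ) -> tuple[Corpus, list[PicoRecord]]:
    """Classify -> filter to title+methods -> tag -> aggregate.

    Returns the corpus (with ``pred_section`` and ``pred_entities``
    populated) and one :class:`PicoRecord` per document.
    """
    for ab in abstracts:
        classify_abstract(config.classifier, ab,
                          trust_headings=config.trust_headings,
                          monotone=config.monotone_sections)
    use = "gold" if config.trust_headings else "pred"
    body_sections = {s for s in config.sections_to_tag if s is not SectionLabel.TITLE}
    tag_corpus(config.tagger, abstracts, sections_to_tag=body_sections,
               use_sections=use)
    records = [build_pico_record(ab) for ab in abstracts]
    return abstracts, records
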