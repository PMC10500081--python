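"""Core domain model for PICO extraction from RCT abstracts.

An :class:`Abstract` is a title plus an ordered list of sentences, each
sentence optionally carrying a gold and/or predicted rhetorical section
label.  PICO mentions are flat, non-overlapping character-offset spans
(:class:`EntitySpan`) anchored to one sentence.  All offsets are 0-based,
half-open ``[start, end)``.

The title is modeled as a pseudo-sentence with the reserved sentence id
``TITLE_SID`` (= -1) and the fixed section label ``title``; it is assigned
structurally and never passes through the section classifier.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Optional

#: Reserved sentence id for the title pseudo-sentence.
TITLE_SID = -1


class SectionLabel(str, enum.Enum):
    """Rhetorical section of an RCT abstract.

    ``objective`` never appears here: upstream normalization folds it into
    ``background``, which is the label set the classifier is trained on.
    """

    TITLE = "title"
    BACKGROUND = "background"
    METHODS = "methods"
    RESULTS = "results"
    CONCLUSIONS = "conclusions"

    def __str__(self) -> str:  # cleaner serialization
        return self.value


#: The four labels the sentence classifier predicts, in canonical order
#: (also the tie-break order: earlier wins).
CLASSIFIABLE_SECTIONS: tuple[SectionLabel, ...] = (
    SectionLabel.BACKGROUND,
    SectionLabel.METHODS,
    SectionLabel.RESULTS,
    SectionLabel.CONCLUSIONS,
)

#: Section order used in coverage tables: Title, Background, Methods,
#: Results, Conclusions.
SECTION_ORDER: tuple[SectionLabel, ...] = (
    SectionLabel.TITLE,
    SectionLabel.BACKGROUND,
    SectionLabel.METHODS,
    SectionLabel.RESULTS,
    SectionLabel.CONCLUSIONS,
)


class EntityClass(str, enum.Enum):
    """The four PICO evidence elements, annotated at a single level."""

    P = "P"  # Population / Participants
    I = "I"  # Intervention
    C = "C"  # Comparison / Control
    O = "O"  # Outcome

    def __str__(self) -> str:
        return self.value


ENTITY_CLASSES: tuple[EntityClass, ...] = (
    EntityClass.P,
    EntityClass.I,
    EntityClass.C,
    EntityClass.O,
)


@dataclass(frozen=True)
class Token:
    """A token with character offsets into its parent sentence text."""

    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid token offsets [{self.start}, {self.end})")


@dataclass
class Sentence:
    """One sentence of an abstract (or the title pseudo-sentence)."""

    sid: int
    text: str
    tokens: list[Token] = field(default_factory=list)
    gold_section: Optional[SectionLabel] = None
    pred_section: Optional[SectionLabel] = None

    @property
    def is_title(self) -> bool:
        return self.sid == TITLE_SID

    def effective_section(self, prefer: str = "pred") -> Optional[SectionLabel]:
        """Section label to act on: 'pred', 'gold', or 'pred' falling back to gold."""
        if self.is_title:
            return SectionLabel.TITLE
        if prefer == "gold":
            return self.gold_section
        if prefer == "pred":
            return self.pred_section
        raise ValueError(f"unknown preference {prefer!r}")

    def token_boundaries(self) -> tuple[set[int], set[int]]:
        starts = {t.start for t in self.tokens}
        ends = {t.end for t in self.tokens}
        return starts, ends


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A PICO mention: a character-offset interval within one sentence.

    ``sid`` is the sentence index (``TITLE_SID`` for the title); offsets are
    0-based half-open within that sentence's text.  ``text`` is redundant
    and re-validated against the sliced sentence text on load.
    """

    sid: int
    start: int
    end: int
    cls: EntityClass
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span offsets [{self.start}, {self.end}) for {self.text!r}"
            )

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.sid == other.sid and self.start < other.end and other.start < self.end


@dataclass
class Abstract:
    """A document: title + ordered sentences + flat entity annotations.

    ``entities`` holds gold spans, ``pred_entities`` holds system output;
    both obey the same flatness invariant.  ``structured`` records whether
    the source document carried recognizable section headings.
    """

    doc_id: str
    title: str
    sentences: list[Sentence] = field(default_factory=list)
    entities: list[EntitySpan] = field(default_factory=list)
    structured: bool = False
    pred_entities: list[EntitySpan] = field(default_factory=list)
    _title_sentence: Optional[Sentence] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")

    @property
    def title_sentence(self) -> Sentence:
        """The title as a pseudo-sentence (sid = TITLE_SID, section = title)."""
        if self._title_sentence is None or self._title_sentence.text != self.title:
            from .corpus_io import tokenize  # deferred: avoids import cycle

            self._title_sentence = Sentence(
                sid=TITLE_SID,
                text=self.title,
                tokens=tokenize(self.title),
                gold_section=SectionLabel.TITLE,
                pred_section=SectionLabel.TITLE,
            )
        return self._title_sentence

    def all_sentences(self) -> Iterator[Sentence]:
        """Title pseudo-sentence first, then body sentences in order."""
        yield self.title_sentence
        yield from self.sentences

    def get_sentence(self, sid: int) -> Sentence:
        if sid == TITLE_SID:
            return self.title_sentence
        for s in self.sentences:
            if s.sid == sid:
                return s
        raise KeyError(f"no sentence {sid} in document {self.doc_id}")

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        sids = [s.sid for s in self.sentences]
        if sids != list(range(len(sids))):
            raise ValueError(f"{self.doc_id}: sentence ids not contiguous from 0: {sids}")
        for group in (self.entities, self.pred_entities):
            ordered = sorted(group)
            for a, b in zip(ordered, ordered[1:]):
                if a.overlaps(b):
                    raise ValueError(
                        f"{self.doc_id}: overlapping spans {a} and {b} "
                        "(annotation schema is flat)"
                    )
            for span in group:
                sent = self.get_sentence(span.sid)  # raises KeyError if dangling
                sliced = sent.text[span.start : span.end]
                if sliced != span.text:
                    raise ValueError(
                        f"{self.doc_id}: span text {span.text!r} does not match "
                        f"sentence slice {sliced!r} (sid={span.sid})"
                    )


Corpus = list[Abstract]


def validate_corpus(corpus: Corpus) -> None:
    seen: set[str] = set()
    for ab in corpus:
        if ab.doc_id in seen:
            raise ValueError(f"duplicate doc_id {ab.doc_id!r} in corpus")
        seen.add(ab.doc_id)
        ab.validate()
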