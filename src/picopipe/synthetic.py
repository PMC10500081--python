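"""Synthetic annotated RCT-like abstracts with known structure.

The generator targets the statistical structure of structured trial
abstracts, not fluent prose: four rhetorical sections in fixed order
(background, methods, results, conclusions) with section-specific
vocabulary, a title carrying population and intervention phrases, PICO
entity spans planted only in the title and methods sentences, and —
mimicking how trial reports restate interventions and outcomes — optional
verbatim unannotated copies of methods entity phrases in the results
section.

Entity phrases come from class-specific lexicons:

* P — cohort patterns, ``"<N> patients with <condition>"``;
* I — drug/dose patterns, ``"<drug> <N> mg"``;
* C — comparator phrases, dominated by placebo variants (a configurable
  fraction), since placebo-heavy control arms are the characteristic
  failure mode real taggers over-fit to;
* O — endpoint patterns, ``"<measure> score"``.

In the *separable* variant every section's filler vocabulary is disjoint
from every other section's and from all entity lexicons, so a consistent
learner can reach near-perfect accuracy; this is the harness used for
parameter-recovery tests.

Each document draws from its own random stream keyed by ``(seed, doc
index)``, so corpora are bit-reproducible and stable under changes to
``n_docs``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .corpus_io import tokenize
from .types import (
    TITLE_SID,
    Abstract,
    Corpus,
    EntityClass,
    EntitySpan,
    SectionLabel,
    Sentence,
)

# ---------------------------------------------------------------------------
# Vocabulary: section fillers are pairwise disjoint by construction, and
# disjoint from every entity lexicon below (checked by tests).
# ---------------------------------------------------------------------------

SECTION_FILLER: dict[SectionLabel, tuple[str, ...]] = {
    SectionLabel.TITLE: (
        "randomized", "controlled", "trial", "of", "for",
    ),
    SectionLabel.BACKGROUND: (
        "burden", "remains", "a", "major", "challenge", "worldwide",
        "prior", "evidence", "is", "limited", "regarding", "optimal",
        "management", "strategies", "little", "known", "about",
        "longterm", "benefit", "existing", "therapies", "uncertain",
    ),
    SectionLabel.METHODS: (
        "we", "enrolled", "participants", "were", "randomly", "assigned",
        "to", "receive", "or", "the", "primary", "endpoint", "was",
        "secondary", "this", "doubleblind", "study", "conducted", "at",
        "three", "centers", "eligibility", "required", "informed",
        "consent", "stratified", "by", "site",
    ),
    SectionLabel.RESULTS: (
        "mean", "change", "from", "baseline", "differed", "significantly",
        "between", "groups", "during", "followup", "treated", "group",
        "showed", "greater", "improvement", "than", "comparator", "arm",
        "adverse", "events", "similar", "across", "arms",
    ),
    SectionLabel.CONCLUSIONS: (
        "in", "conclusion", "these", "findings", "support", "use",
        "further", "research", "warranted", "results", "indicate",
        "therapy", "effective", "and", "well", "tolerated", "overall",
        "larger", "trials", "needed",
    ),
}

#: Words mixed into every section when section_vocab_overlap > 0.
SHARED_FILLER: tuple[str, ...] = (
    "clinical", "data", "analysis", "period", "total", "weeks",
    "protocol", "visit",
)

# Entity lexicon building blocks: pronounceable invented stems, disjoint
# from all filler vocabulary and from one another.
_CONDITION_STEMS = (
    "velorosis", "tandrophy", "quillitis", "morbrexia", "saldenosis",
    "crytopenia", "famblitis", "nordexia", "pellagrosis", "wintrophy",
    "gastrelia", "lumenosis",
)
_DRUG_STEMS = (
    "alfaximab", "betanovir", "corizumab", "deltastat", "exaprofen",
    "feroplatin", "galavudine", "hexarelin", "ilotride", "juvastine",
    "keraxolol", "loravir",
)
_MEASURE_STEMS = (
    "cardex", "neurofax", "oxilern", "pulmovar", "dermatrix",
    "hemoquant", "visiline", "motricel", "somnogra", "renaflux",
    "glycotra", "audimet",
)
#: Comparator phrases; the first entries are placebo variants.
_PLACEBO_PHRASES = ("placebo", "matching placebo", "oral placebo")
_ACTIVE_CONTROL_PHRASES = ("usual care", "standard care", "sham injection")

#: Dose values (mg) for intervention phrases; disjoint from the cohort-size
#: range below so every number belongs to exactly one entity class.
_DOSES = (12, 24, 36, 48, 60, 72)
_COHORT_LOW, _COHORT_HIGH = 100, 300  # cohort sizes are 3-digit, doses 2-digit


class SynthConfig(BaseModel):
    """Configuration of the synthetic corpus generator.

    Fractions live in [0, 1]; identical configs produce bit-identical
    corpora.  ``label_noise`` flips that fraction of gold section labels
    and exists for robustness experiments only — it is off by default.
    """

    n_docs: int = Field(default=100, ge=0)
    seed: int = Field(default=0, ge=0)
    section_vocab_overlap: float = Field(default=0.0, ge=0.0, le=1.0)
    entities_per_methods_sentence: float = Field(default=1.0, ge=0.0)
    cross_section_repeat_prob: float = Field(default=0.3, ge=0.0, le=1.0)
    label_noise: float = Field(default=0.0, ge=0.0, le=1.0)
    placebo_frequency: float = Field(default=0.6, ge=0.0, le=1.0)
    lexicon_sizes: dict[str, int] = Field(
        default_factory=lambda: {"P": 12, "I": 12, "C": 6, "O": 12}
    )

    @field_validator("lexicon_sizes")
    @classmethod
    def _check_lexicons(cls, v: dict[str, int]) -> dict[str, int]:
        for key, size in v.items():
            if key not in {"P", "I", "C", "O"}:
                raise ValueError(f"unknown entity class {key!r}")
            if size < 1:
                raise ValueError(f"lexicon size for {key} must be >= 1")
        limits = {"P": len(_CONDITION_STEMS), "I": len(_DRUG_STEMS),
                  "C": len(_PLACEBO_PHRASES) + len(_ACTIVE_CONTROL_PHRASES),
                  "O": len(_MEASURE_STEMS)}
        for key, size in v.items():
            if size > limits[key]:
                raise ValueError(f"lexicon size for {key} exceeds {limits[key]}")
        return v


def class_lexicon_tokens(config: Optional[SynthConfig] = None) -> dict[EntityClass, set[str]]:
    """Casefolded token inventory of each class lexicon (for audits)."""
    config = config or SynthConfig()
    sizes = config.lexicon_sizes
    p_tokens = {"patients", "with"} | set(_CONDITION_STEMS[: sizes["P"]])
    p_tokens |= {str(n) for n in range(_COHORT_LOW, _COHORT_HIGH)}
    i_tokens = {"mg"} | set(_DRUG_STEMS[: sizes["I"]]) | {str(d) for d in _DOSES}
    c_phrases = (_PLACEBO_PHRASES + _ACTIVE_CONTROL_PHRASES)[: sizes["C"]]
    c_tokens = {w for ph in c_phrases for w in ph.split()}
    o_tokens = {"score"} | set(_MEASURE_STEMS[: sizes["O"]])
    return {EntityClass.P: p_tokens, EntityClass.I: i_tokens,
            EntityClass.C: c_tokens, EntityClass.O: o_tokens}


# ---------------------------------------------------------------------------
# Per-document generation
# ---------------------------------------------------------------------------


def _filler(rng: np.random.Generator, section: SectionLabel, k: int,
            overlap: float) -> list[str]:
    words = []
    pool = SECTION_FILLER[section]
    for _ in range(k):
        if overlap > 0 and rng.random() < overlap:
            words.append(str(rng.choice(SHARED_FILLER)))
        else:
            words.append(str(rng.choice(pool)))
    return words


def _filler_sentence(rng: np.random.Generator, section: SectionLabel,
                     overlap: float) -> str:
    k = int(rng.integers(5, 10))
    words = _filler(rng, section, k, overlap)
    words[0] = words[0].capitalize()
    return " ".join(words) + "."


def _entity_sentence(prefix: list[str], phrases: list[tuple[str, EntityClass]],
                     joiner_words: list[list[str]], suffix: list[str],
                     sid: int) -> tuple[Sentence, list[EntitySpan]]:
    """Assemble ``prefix ph0 j0 ph1 j1 ... suffix.`` tracking span offsets."""
    parts: list[str] = []
    spans: list[tuple[int, int, EntityClass, str]] = []
    cursor = 0

    def push(words: list[str]) -> None:
        nonlocal cursor
        for w in words:
            if parts:
                cursor += 1  # joining space
            parts.append(w)
            cursor += len(w)

    push(prefix)
    for idx, (phrase, cls) in enumerate(phrases):
        if parts:
            cursor += 1
        start = cursor
        parts.append(phrase)
        cursor += len(phrase)
        spans.append((start, cursor, cls, phrase))
        if idx < len(joiner_words):
            push(joiner_words[idx])
    push(suffix)
    text = " ".join(parts)
    if parts and parts[0][0].islower():
        text = text[0].upper() + text[1:]
    text += "."
    sent = Sentence(sid=sid, text=text, tokens=tokenize(text))
    entity_spans = [
        EntitySpan(sid=sid, start=s, end=e, cls=c, text=text[s:e])
        for (s, e, c, _p) in spans
    ]
    return sent, entity_spans


def _make_document(doc_index: int, config: SynthConfig) -> Abstract:
    rng = np.random.default_rng([config.seed, doc_index])
    sizes = config.lexicon_sizes
    overlap = config.section_vocab_overlap

    condition = _CONDITION_STEMS[int(rng.integers(0, sizes["P"]))]
    drug = _DRUG_STEMS[int(rng.integers(0, sizes["I"]))]
    dose = int(rng.choice(_DOSES))
    measure = _MEASURE_STEMS[int(rng.integers(0, sizes["O"]))]
    n_cohort = int(rng.integers(_COHORT_LOW, _COHORT_HIGH))

    p_phrase = f"{n_cohort} patients with {condition}"
    i_phrase = f"{drug} {dose} mg"
    c_pool = (_PLACEBO_PHRASES + _ACTIVE_CONTROL_PHRASES)[: sizes["C"]]
    n_placebo = sum(1 for ph in c_pool if "placebo" in ph)
    if n_placebo and rng.random() < config.placebo_frequency:
        c_phrase = c_pool[int(rng.integers(0, n_placebo))]
    else:
        active = c_pool[n_placebo:] or c_pool
        c_phrase = active[int(rng.integers(0, len(active)))]
    o_phrase = f"{measure} score"

    entities: list[EntitySpan] = []

    # Title: always carries >= 1 P and >= 1 I phrase.
    title_prefix = ["Randomized", "trial", "of"]
    title_parts = title_prefix + [i_phrase, "for", p_phrase]
    title = " ".join(title_parts)
    i_start = len(" ".join(title_prefix)) + 1
    entities.append(EntitySpan(sid=TITLE_SID, start=i_start,
                               end=i_start + len(i_phrase),
                               cls=EntityClass.I, text=i_phrase))
    p_start = i_start + len(i_phrase) + len(" for ")
    entities.append(EntitySpan(sid=TITLE_SID, start=p_start,
                               end=p_start + len(p_phrase),
                               cls=EntityClass.P, text=p_phrase))

    sentences: list[Sentence] = []

    def add_filler(section: SectionLabel, n: int) -> None:
        for _ in range(n):
            s = Sentence(sid=len(sentences),
                         text=_filler_sentence(rng, section, overlap),
                         gold_section=section)
            s.tokens = tokenize(s.text)
            sentences.append(s)

    # Background
    add_filler(SectionLabel.BACKGROUND, int(rng.integers(2, 4)))

    # Methods: three templated entity sentences + optional filler + extras.
    methods_specs: list[tuple[list[str], list[tuple[str, EntityClass]],
                              list[list[str]], list[str]]] = [
        (["we", "enrolled"], [(p_phrase, EntityClass.P)], [], []),
        (["participants", "were", "randomly", "assigned", "to", "receive"],
         [(i_phrase, EntityClass.I), (c_phrase, EntityClass.C)], [["or"]], []),
        (["the", "primary", "endpoint", "was"], [(o_phrase, EntityClass.O)],
         [], []),
    ]
    n_methods_filler = int(rng.integers(0, 2))
    n_methods_base = len(methods_specs) + n_methods_filler
    target_mentions = round(config.entities_per_methods_sentence * n_methods_base)
    extra = max(0, target_mentions - 4)
    for j in range(extra):
        # alternate extra outcome / intervention mentions with fresh picks
        if j % 2 == 0:
            m2 = _MEASURE_STEMS[int(rng.integers(0, sizes["O"]))]
            methods_specs.append((["the", "secondary", "endpoint", "was"],
                                  [(f"{m2} score", EntityClass.O)], [], []))
        else:
            d2 = _DRUG_STEMS[int(rng.integers(0, sizes["I"]))]
            methods_specs.append((["participants", "assigned", "to"],
                                  [(f"{d2} {int(rng.choice(_DOSES))} mg",
                                    EntityClass.I)], [], []))

    methods_phrases: list[str] = []
    for spec in methods_specs:
        sent, spans = _entity_sentence(*spec, sid=len(sentences))
        sent.gold_section = SectionLabel.METHODS
        sentences.append(sent)
        entities.extend(spans)
        methods_phrases.extend(sp.text for sp in spans)
    add_filler(SectionLabel.METHODS, n_methods_filler)

    # Results: filler + unannotated verbatim repeats of methods phrases.
    add_filler(SectionLabel.RESULTS, int(rng.integers(1, 3)))
    for phrase in methods_phrases:
        if rng.random() < config.cross_section_repeat_prob:
            text = f"Mean {phrase} differed significantly between groups."
            s = Sentence(sid=len(sentences), text=text, tokens=tokenize(text),
                         gold_section=SectionLabel.RESULTS)
            sentences.append(s)

    # Conclusions
    add_filler(SectionLabel.CONCLUSIONS, int(rng.integers(1, 3)))

    # Optional gold-label noise (robustness experiments only).
    if config.label_noise > 0:
        others = {
            sec: [o for o in (SectionLabel.BACKGROUND, SectionLabel.METHODS,
                              SectionLabel.RESULTS, SectionLabel.CONCLUSIONS)
                  if o is not sec]
            for sec in SECTION_FILLER
        }
        for s in sentences:
            if rng.random() < config.label_noise:
                s.gold_section = others[s.gold_section][int(rng.integers(0, 3))]

    ab = Abstract(doc_id=f"synth-{config.seed}-{doc_index:05d}", title=title,
                  sentences=sentences, entities=entities, structured=True)
    ab.validate()
    return ab


def generate_corpus(config: Optional[SynthConfig] = None, **kwargs) -> Corpus:
    """Generate an annotated corpus; see :class:`SynthConfig` for knobs."""
    if config is None:
        config = SynthConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config object or keyword overrides, not both")
    return [_make_document(i, config) for i in range(config.n_docs)]


def generate_separable_corpus(config: Optional[SynthConfig] = None, **kwargs) -> Corpus:
    """Corpus variant with fully disjoint section/entity vocabularies.

    Forces ``section_vocab_overlap = 0`` so each rhetorical section uses a
    vocabulary no other section shares and entity tokens occur in exactly
    one class lexicon.  A consistent learner can reach near-perfect
    accuracy here; used for parameter-recovery tests.
    """
    if config is None:
        config = SynthConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config object or keyword overrides, not both")
    config = config.model_copy(update={"section_vocab_overlap": 0.0})
    return generate_corpus(config)
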