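"""Section-coverage analysis of PICO mentions.

For a set of annotated abstracts, count how many of the unique PICO
mentions of each class appear in each rhetorical section (title,
background, methods, results, conclusions), and derive each section's
*coverage*: the fraction of all unique mentions that the section
contains,

    coverage[s] = (sum_c counts[c][s]) / (sum_c totals[c]),

reported half-up to 3 decimals.  "Unique mention" means deduplication by
normalized string (casefold + whitespace collapse) within class, per
document; totals aggregate those per-document unique mentions over the
document set.  A mention "appears" in a section when its normalized
string occurs in any sentence of that section, so unannotated repeats in
results/conclusions are found by string search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Mapping, Union

from .pipeline import build_pico_record, normalize_mention
from .types import (
    ENTITY_CLASSES,
    SECTION_ORDER,
    Corpus,
    EntityClass,
    SectionLabel,
)

#: Conventional column abbreviations for the five sections.
SECTION_ABBREV: dict[SectionLabel, str] = {
    SectionLabel.TITLE: "TT",
    SectionLabel.BACKGROUND: "BG",
    SectionLabel.METHODS: "MT",
    SectionLabel.RESULTS: "RS",
    SectionLabel.CONCLUSIONS: "CC",
}


def _round3(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


@dataclass
class CoverageTable:
    """Per-section, per-class unique-mention counts plus the coverage row."""

    counts: dict[EntityClass, dict[SectionLabel, int]]
    totals: dict[EntityClass, int]
    coverage: dict[SectionLabel, float] = field(init=False)

    def __post_init__(self) -> None:
        for cls in ENTITY_CLASSES:
            for sec in SECTION_ORDER:
                c = self.counts[cls][sec]
                if c < 0:
                    raise ValueError(f"negative count for {cls}/{sec}")
                if c > self.totals[cls]:
                    raise ValueError(
                        f"count {c} for {cls.value} in {SECTION_ABBREV[sec]} "
                        f"exceeds class total {self.totals[cls]}"
                    )
        grand_total = sum(self.totals[cls] for cls in ENTITY_CLASSES)
        self.coverage = {}
        for sec in SECTION_ORDER:
            col = sum(self.counts[cls][sec] for cls in ENTITY_CLASSES)
            self.coverage[sec] = _round3(col / grand_total) if grand_total else 0.0

    def to_tsv(self) -> str:
        header = "Entity\t" + "\t".join(SECTION_ABBREV[s] for s in SECTION_ORDER) + "\tTotal"
        lines = [header]
        for cls in ENTITY_CLASSES:
            row = [cls.value] + [str(self.counts[cls][s]) for s in SECTION_ORDER]
            row.append(str(self.totals[cls]))
            lines.append("\t".join(row))
        cov = ["Coverage"] + [f"{self.coverage[s]:.3f}" for s in SECTION_ORDER] + [""]
        lines.append("\t".join(cov))
        return "\n".join(lines) + "\n"


CountsLike = Mapping[Union[EntityClass, str], Mapping[Union[SectionLabel, str], int]]


def _as_class(c: Union[EntityClass, str]) -> EntityClass:
    return c if isinstance(c, EntityClass) else EntityClass(c)


def _as_section(s: Union[SectionLabel, str]) -> SectionLabel:
    if isinstance(s, SectionLabel):
        return s
    by_abbrev = {v: k for k, v in SECTION_ABBREV.items()}
    return by_abbrev.get(s.upper()) or SectionLabel(s.lower())


def compute_coverage_from_counts(counts: CountsLike,
                                 totals: Mapping[Union[EntityClass, str], int]
                                 ) -> CoverageTable:
    """Build a coverage table from already-tallied counts.

    ``counts[class][section]`` accepts class values (``"P"``...) and
    sections as labels or the TT/BG/MT/RS/CC abbreviations.  Missing
    cells default to 0; a count exceeding its class total is an error.
    """
    norm_counts: dict[EntityClass, dict[SectionLabel, int]] = {
        cls: {sec: 0 for sec in SECTION_ORDER} for cls in ENTITY_CLASSES
    }
    for c, row in counts.items():
        cls = _as_class(c)
        for s, v in row.items():
            norm_counts[cls][_as_section(s)] = int(v)
    norm_totals = {cls: 0 for cls in ENTITY_CLASSES}
    for c, v in totals.items():
        norm_totals[_as_class(c)] = int(v)
    return CoverageTable(counts=norm_counts, totals=norm_totals)


def coverage_from_corpus(corpus: Corpus) -> CoverageTable:
    """Compute the coverage table directly from an annotated corpus.

    Requires gold section labels on every body sentence (the title is
    labeled structurally).  Unique mentions come from gold entity spans;
    their presence in each section is decided by normalized substring
    search over that section's sentences, which also finds unannotated
    repeats outside the annotated sections.
    """
    counts: dict[EntityClass, dict[SectionLabel, int]] = {
        cls: {sec: 0 for sec in SECTION_ORDER} for cls in ENTITY_CLASSES
    }
    totals = {cls: 0 for cls in ENTITY_CLASSES}
    for ab in corpus:
        section_text: dict[SectionLabel, list[str]] = {sec: [] for sec in SECTION_ORDER}
        section_text[SectionLabel.TITLE].append(normalize_mention(ab.title))
        for sent in ab.sentences:
            if sent.gold_section is None:
                raise ValueError(
                    f"{ab.doc_id}: sentence {sent.sid} lacks a section label; "
                    "coverage needs fully sectioned documents"
                )
            section_text[sent.gold_section].append(normalize_mention(sent.text))
        record = build_pico_record(ab, spans=ab.entities)
        for cls in ENTITY_CLASSES:
            mentions = record.unique_strings(cls)
            totals[cls] += len(mentions)
            for sec in SECTION_ORDER:
                blob = " \n ".join(section_text[sec])
                counts[cls][sec] += sum(1 for m in mentions if m in blob)
    return CoverageTable(counts=counts, totals=totals)


def read_counts_tsv(source: Union[str, IO[str]]) -> CoverageTable:
    """Read a coverage-table TSV (the :meth:`CoverageTable.to_tsv` layout).

    Expects a header row naming the five section columns plus ``Total``
    and one row per entity class; a trailing Coverage row, if present, is
    ignored and recomputed.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    section_cols = [(i, _as_section(h)) for i, h in enumerate(header)
                    if h.strip().upper() in SECTION_ABBREV.values()]
    total_col = next(i for i, h in enumerate(header) if h.strip().lower() == "total")
    counts: dict[EntityClass, dict[SectionLabel, int]] = {}
    totals: dict[EntityClass, int] = {}
    for ln in lines[1:]:
        cells = ln.split("\t")
        if cells[0].strip().lower() == "coverage":
            continue
        cls = EntityClass(cells[0].strip())
        counts[cls] = {sec: int(cells[i]) for i, sec in section_cols}
        totals[cls] = int(cells[total_col])
    return compute_coverage_from_counts(counts, totals)
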