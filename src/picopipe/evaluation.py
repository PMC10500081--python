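"""Scoring: token-level, entity-level (exact/partial), end-to-end,
confusion matrices, Cohen's kappa and cross-validation splitting.

Conventions
-----------
* Token-level scoring collapses ``B-c``/``I-c`` to the entity class ``c``
  and *excludes Outside agreement*: a token with gold = pred = Outside
  contributes nothing, so scores reflect entity tokens only.  In the
  collapsed representation Outside is written ``"OUT"`` to keep it
  distinct from the Outcome class ``"O"``.
* Entity-level exact match requires identical ``(sid, start, end, class)``.
  Partial match is a greedy one-to-one matching of same-class spans that
  share at least one token, longest token overlap first, ties broken by
  earlier gold start; unmatched predictions are FP, unmatched gold FN.
* Micro-averaged scores are always recomputed from the *summed* TP/FP/FN
  over classes, never by averaging per-class scores.
* All 0/0 ratios are defined as 0 (and logged once at debug level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Optional, Sequence

import numpy as np

from .corpus_io import spans_to_bio
from .types import (
    ENTITY_CLASSES,
    Abstract,
    Corpus,
    EntityClass,
    EntitySpan,
    Sentence,
)

logger = logging.getLogger(__name__)

Granularity = Literal["token", "entity_exact", "entity_partial", "sentence_class"]

_CLASS_ORDER = [c.value for c in ENTITY_CLASSES]

#: Collapsed-label symbol for Outside tokens (distinct from Outcome "O").
OUTSIDE = "OUT"


def _safe_div(num: float, den: float) -> float:
    if den == 0:
        logger.debug("0/0 ratio encountered; defined as 0")
        return 0.0
    return num / den


@dataclass(frozen=True)
class ClassScores:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return _safe_div(self.tp, self.tp + self.fp)

    @property
    def recall(self) -> float:
        return _safe_div(self.tp, self.tp + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return _safe_div(2 * p * r, p + r)


@dataclass
class EvalReport:
    """Per-class TP/FP/FN with derived P/R/F1 and micro-averaged overall row."""

    granularity: Granularity
    per_class: dict[str, ClassScores]
    class_order: list[str] = field(default_factory=lambda: list(_CLASS_ORDER))

    @classmethod
    def from_counts(cls, granularity: Granularity,
                    counts: dict[str, tuple[int, int, int]],
                    class_order: Optional[Sequence[str]] = None) -> "EvalReport":
        per_class = {k: ClassScores(*v) for k, v in counts.items()}
        order = list(class_order) if class_order else list(counts)
        return cls(granularity=granularity, per_class=per_class,
                   class_order=order)

    @property
    def micro(self) -> ClassScores:
        """Overall scores from summed counts (never averaged per-class scores)."""
        tp = sum(s.tp for s in self.per_class.values())
        fp = sum(s.fp for s in self.per_class.values())
        fn = sum(s.fn for s in self.per_class.values())
        return ClassScores(tp, fp, fn)

    @property
    def macro_f1(self) -> float:
        """Unweighted mean of per-class F1 (reported for contrast only)."""
        vals = [self.per_class[c].f1 for c in self.class_order]
        return float(np.mean(vals)) if vals else 0.0

    def to_dict(self) -> dict:
        """Table layout: one row per class plus an Overall row."""
        rows = {}
        for c in self.class_order:
            s = self.per_class.get(c, ClassScores(0, 0, 0))
            rows[c] = {"tp": s.tp, "fp": s.fp, "fn": s.fn,
                       "precision": round(s.precision, 3),
                       "recall": round(s.recall, 3),
                       "f1": round(s.f1, 3)}
        m = self.micro
        rows["Overall"] = {"tp": m.tp, "fp": m.fp, "fn": m.fn,
                           "precision": round(m.precision, 3),
                           "recall": round(m.recall, 3),
                           "f1": round(m.f1, 3)}
        return {"granularity": self.granularity, "classes": rows}


# ---------------------------------------------------------------------------
# Span/tag plumbing
# ---------------------------------------------------------------------------


def _spans_by_sid(spans: Iterable[EntitySpan]) -> dict[int, list[EntitySpan]]:
    out: dict[int, list[EntitySpan]] = {}
    for sp in spans:
        out.setdefault(sp.sid, []).append(sp)
    return out


def sentence_class_labels(sentence: Sentence,
                          spans: Iterable[EntitySpan]) -> list[str]:
    """Per-token entity-class labels (B/I collapsed; Outside = 'OUT')."""
    tags = spans_to_bio(sentence, spans)
    return [OUTSIDE if t == "O" else t[2:] for t in tags]


def _paired(gold: Corpus, pred: Optional[Corpus]) -> list[tuple[Abstract, Abstract]]:
    if pred is None:
        return [(ab, ab) for ab in gold]
    by_id = {ab.doc_id: ab for ab in pred}
    missing = [ab.doc_id for ab in gold if ab.doc_id not in by_id]
    if missing:
        raise ValueError(f"prediction corpus lacks documents: {missing}")
    return [(ab, by_id[ab.doc_id]) for ab in gold]


# ---------------------------------------------------------------------------
# Token-level evaluation
# ---------------------------------------------------------------------------


def token_counts(gold_labels: Sequence[str],
                 pred_labels: Sequence[str]) -> dict[str, list[int]]:
    """Per-class [TP, FP, FN] tallies over aligned class-label sequences.

    Labels are the collapsed entity classes plus :data:`OUTSIDE`.
    Outside/Outside agreement is excluded by construction: only tokens
    where gold or pred is an entity class contribute.
    """
    if len(gold_labels) != len(pred_labels):
        raise ValueError("label sequences have different lengths")
    counts = {c: [0, 0, 0] for c in _CLASS_ORDER}
    for g, p in zip(gold_labels, pred_labels):
        if g == p:
            if g != OUTSIDE:
                counts[g][0] += 1
        else:
            if p != OUTSIDE:
                counts[p][1] += 1
            if g != OUTSIDE:
                counts[g][2] += 1
    return counts


def token_eval(gold: Corpus, pred: Optional[Corpus] = None) -> EvalReport:
    """Token-level scoring of predicted vs gold spans over whole documents.

    ``pred`` defaults to the gold corpus itself, in which case predictions
    are taken from each abstract's ``pred_entities``.  Tokenizations must
    be identical on both sides.
    """
    counts = {c: [0, 0, 0] for c in _CLASS_ORDER}
    for gold_ab, pred_ab in _paired(gold, pred):
        g_by_sid = _spans_by_sid(gold_ab.entities)
        p_by_sid = _spans_by_sid(pred_ab.pred_entities)
        for sent in gold_ab.all_sentences():
            pred_sent = pred_ab.get_sentence(sent.sid) if pred_ab is not gold_ab else sent
            if len(pred_sent.tokens) != len(sent.tokens):
                raise ValueError(
                    f"{gold_ab.doc_id}: token count mismatch at sentence {sent.sid}"
                )
            g = sentence_class_labels(sent, g_by_sid.get(sent.sid, []))
            p = sentence_class_labels(pred_sent, p_by_sid.get(sent.sid, []))
            for c, (tp, fp, fn) in token_counts(g, p).items():
                counts[c][0] += tp
                counts[c][1] += fp
                counts[c][2] += fn
    return EvalReport.from_counts("token", {c: tuple(v) for c, v in counts.items()},
                                  _CLASS_ORDER)


# ---------------------------------------------------------------------------
# Entity-level evaluation
# ---------------------------------------------------------------------------


def _token_range(sentence: Sentence, span: EntitySpan) -> tuple[int, int]:
    """Half-open token-index interval covered by a (token-aligned) span."""
    first = next(i for i, t in enumerate(sentence.tokens) if t.start == span.start)
    last = next(i for i, t in enumerate(sentence.tokens) if t.end == span.end)
    return first, last + 1


def _check_flat(spans: Sequence[EntitySpan], side: str) -> None:
    ordered = sorted(spans)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping {side} spans {a} and {b}")


def greedy_partial_match(
    gold: Sequence[EntitySpan],
    pred: Sequence[EntitySpan],
    sentence_lookup: Callable[[int], Sentence],
) -> list[tuple[EntitySpan, EntitySpan]]:
    """One-to-one same-class matching by token overlap, greedy.

    Candidate pairs share >= 1 token and the same class; pairs are taken
    longest-overlap-first, ties broken by earlier gold start then earlier
    pred start.  Deterministic.
    """
    ranges: dict[tuple[int, int, int], tuple[int, int]] = {}

    def rng_of(sp: EntitySpan) -> tuple[int, int]:
        key = (sp.sid, sp.start, sp.end)
        if key not in ranges:
            ranges[key] = _token_range(sentence_lookup(sp.sid), sp)
        return ranges[key]

    candidates = []
    for gi, g in enumerate(gold):
        for pi, p in enumerate(pred):
            if g.sid != p.sid or g.cls != p.cls:
                continue
            gs, ge = rng_of(g)
            ps, pe = rng_of(p)
            overlap = min(ge, pe) - max(gs, ps)
            if overlap >= 1:
                candidates.append((-overlap, g.sid, g.start, p.start, gi, pi))
    candidates.sort()
    used_g: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for _, _, _, _, gi, pi in candidates:
        if gi in used_g or pi in used_p:
            continue
        used_g.add(gi)
        used_p.add(pi)
        pairs.append((gold[gi], pred[pi]))
    return pairs


def entity_eval(gold: Corpus, pred: Optional[Corpus] = None,
                mode: Literal["exact", "partial"] = "exact") -> EvalReport:
    """Entity-level scoring by exact or partial span match."""
    counts = {c: [0, 0, 0] for c in _CLASS_ORDER}
    for gold_ab, pred_ab in _paired(gold, pred):
        g_spans = list(gold_ab.entities)
        p_spans = list(pred_ab.pred_entities)
        _check_flat(g_spans, "gold")
        _check_flat(p_spans, "predicted")
        if mode == "exact":
            g_keys = {(s.sid, s.start, s.end, s.cls) for s in g_spans}
            p_keys = {(s.sid, s.start, s.end, s.cls) for s in p_spans}
            for s in g_spans:
                key = (s.sid, s.start, s.end, s.cls)
                if key in p_keys:
                    counts[s.cls.value][0] += 1
                else:
                    counts[s.cls.value][2] += 1
            for s in p_spans:
                if (s.sid, s.start, s.end, s.cls) not in g_keys:
                    counts[s.cls.value][1] += 1
        elif mode == "partial":
            pairs = greedy_partial_match(g_spans, p_spans, gold_ab.get_sentence)
            matched_g = {id(g) for g, _ in pairs}
            matched_p = {id(p) for _, p in pairs}
            for g, _ in pairs:
                counts[g.cls.value][0] += 1
            for s in g_spans:
                if id(s) not in matched_g:
                    counts[s.cls.value][2] += 1
            for s in p_spans:
                if id(s) not in matched_p:
                    counts[s.cls.value][1] += 1
        else:
            raise ValueError(f"unknown mode {mode!r}")
    gran: Granularity = "entity_exact" if mode == "exact" else "entity_partial"
    return EvalReport.from_counts(gran, {c: tuple(v) for c, v in counts.items()},
                                  _CLASS_ORDER)


def end_to_end_eval(gold: Corpus, pipeline_output: Optional[Corpus] = None,
                    granularity: Literal["token", "entity_exact",
                                         "entity_partial"] = "entity_exact"
                    ) -> EvalReport:
    """Score the full two-step system against gold annotations.

    Identical metric definitions to the standalone evaluations, applied
    over *all* sentences: spans predicted in misclassified sections count
    as FP and gold spans missed because their sentence was routed away
    from the tagger count as FN.
    """
    if granularity == "token":
        return token_eval(gold, pipeline_output)
    mode = "exact" if granularity == "entity_exact" else "partial"
    return entity_eval(gold, pipeline_output, mode=mode)


# ---------------------------------------------------------------------------
# Confusion matrix
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Square token-level count matrix; rows = gold, columns = predicted."""

    labels: list[str]
    counts: np.ndarray

    def normalized(self) -> np.ndarray:
        """Row-normalized view (rows with no gold tokens stay all-zero)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / sums, 0.0)
        return out

    def to_dict(self) -> dict:
        return {"labels": self.labels,
                "counts": self.counts.astype(int).tolist()}


def confusion(gold: Corpus, pred: Optional[Corpus] = None,
              basis: Literal["class_token", "iob_token"] = "class_token"
              ) -> ConfusionMatrix:
    """Token-level confusion over entity classes + Outside, or full IOB labels."""
    if basis == "class_token":
        labels = _CLASS_ORDER + [OUTSIDE]
        collapse = True
    elif basis == "iob_token":
        from .corpus_io import BIO_LABELS

        labels = list(BIO_LABELS)
        collapse = False
    else:
        raise ValueError(f"unknown basis {basis!r}")
    index = {lab: i for i, lab in enumerate(labels)}
    M = np.zeros((len(labels), len(labels)))
    for gold_ab, pred_ab in _paired(gold, pred):
        g_by_sid = _spans_by_sid(gold_ab.entities)
        p_by_sid = _spans_by_sid(pred_ab.pred_entities)
        for sent in gold_ab.all_sentences():
            pred_sent = pred_ab.get_sentence(sent.sid) if pred_ab is not gold_ab else sent
            if len(pred_sent.tokens) != len(sent.tokens):
                raise ValueError(
                    f"{gold_ab.doc_id}: token count mismatch at sentence {sent.sid}"
                )
            g_tags = spans_to_bio(sent, g_by_sid.get(sent.sid, []))
            p_tags = spans_to_bio(pred_sent, p_by_sid.get(sent.sid, []))
            if collapse:
                g_tags = [OUTSIDE if t == "O" else t[2:] for t in g_tags]
                p_tags = [OUTSIDE if t == "O" else t[2:] for t in p_tags]
            for g, p in zip(g_tags, p_tags):
                M[index[g], index[p]] += 1
    return ConfusionMatrix(labels=labels, counts=M)


# ---------------------------------------------------------------------------
# Cohen's kappa (inter-annotator agreement)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KappaResult:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e)."""

    p_o: float
    p_e: float
    kappa: float
    basis: str
    n_tokens: int


def kappa_from_labels(labels_a: Sequence[str], labels_b: Sequence[str],
                      basis: str = "all") -> KappaResult:
    """Cohen's kappa over two aligned per-token label sequences.

    ``p_o`` is the observed agreement fraction; ``p_e`` the chance
    agreement from the two annotators' label marginals.  Perfect agreement
    with ``p_e = 1`` (both annotators constant and identical) is defined
    as kappa 1.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("annotations cover different token counts")
    n = len(labels_a)
    if n == 0:
        raise ValueError("cannot compute agreement over zero tokens")
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    p_o = float(np.mean(a == b))
    inventory = sorted(set(labels_a) | set(labels_b))
    p_e = float(sum(np.mean(a == lab) * np.mean(b == lab) for lab in inventory))
    if p_e >= 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return KappaResult(p_o=p_o, p_e=p_e, kappa=kappa, basis=basis, n_tokens=n)


def cohens_kappa(annotation_a: Corpus, annotation_b: Corpus,
                 basis: str = "all") -> KappaResult:
    """Token-level kappa between two annotations of the same text.

    With ``basis='all'`` tokens carry entity-class labels with O included;
    with a class value (``'P'``...) labels are binarized to class vs rest.
    Both corpora must tokenize identically.
    """
    flat_a: list[str] = []
    flat_b: list[str] = []
    for ab_a, ab_b in _paired(annotation_a, annotation_b):
        a_by_sid = _spans_by_sid(ab_a.entities)
        b_by_sid = _spans_by_sid(ab_b.entities)
        for sent in ab_a.all_sentences():
            sent_b = ab_b.get_sentence(sent.sid)
            if len(sent_b.tokens) != len(sent.tokens):
                raise ValueError(
                    f"{ab_a.doc_id}: annotators tokenize sentence {sent.sid} "
                    "differently"
                )
            flat_a.extend(sentence_class_labels(sent, a_by_sid.get(sent.sid, [])))
            flat_b.extend(sentence_class_labels(sent_b, b_by_sid.get(sent.sid, [])))
    if basis != "all":
        cls = EntityClass(basis).value
        flat_a = [("1" if lab == cls else "0") for lab in flat_a]
        flat_b = [("1" if lab == cls else "0") for lab in flat_b]
    return kappa_from_labels(flat_a, flat_b, basis=basis)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def kfold_split(corpus: Corpus, k: int, seed: int = 0
                ) -> list[tuple[Corpus, Corpus]]:
    """Document-level k-fold partition (never splits by sentence).

    Folds are disjoint and exhaustive, deterministic per seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(corpus):
        raise ValueError(f"k={k} exceeds corpus size {len(corpus)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    folds = np.array_split(order, k)
    out = []
    for i in range(k):
        test_idx = set(folds[i].tolist())
        test = [corpus[j] for j in sorted(test_idx)]
        train = [corpus[j] for j in range(len(corpus)) if j not in test_idx]
        out.append((train, test))
    return out


def cv_report(corpus: Corpus, k: int, seed: int,
              run_fold: Callable[[Corpus, Corpus], EvalReport]) -> dict:
    """Average fold-level micro P/R/F1 over a k-fold split.

    ``run_fold(train, test)`` trains on the fold's training documents and
    returns an :class:`EvalReport` on its test documents.  The summary is
    the *mean of fold-level micro scores* (not pooled counts).
    """
    reports = [run_fold(train, test) for train, test in kfold_split(corpus, k, seed)]
    micro = [r.micro for r in reports]
    return {
        "k": k,
        "precision": float(np.mean([m.precision for m in micro])),
        "recall": float(np.mean([m.recall for m in micro])),
        "f1": float(np.mean([m.f1 for m in micro])),
        "folds": [r.to_dict() for r in reports],
    }
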