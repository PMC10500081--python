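"""Sentence-level rhetorical section classification.

Every non-title sentence of an abstract is assigned one of
``{background, methods, results, conclusions}``.  The title is labeled
structurally and never passes through the classifier.

The default backend is a regularized multinomial logistic-regression model
over sparse lexical features with context from the neighboring sentences
(bag of tokens of the previous/next sentence, relative position, first/last
flags) — the desk-scale member of the same family of context-sensitive
sentence classifiers used for structured-abstract sectioning.  A
transformer backend (prompt-style fine-tuning) is an optional adapter
behind the same contract; see :mod:`picopipe.backends`.

Predicted-class ties break toward the earlier label in the fixed order
(background, methods, results, conclusions).
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .types import (
    CLASSIFIABLE_SECTIONS,
    Abstract,
    Corpus,
    SectionLabel,
    Sentence,
)

logger = logging.getLogger(__name__)

FEATURE_SPEC_VERSION = "sentfeat-v1"

_LABEL_ORDER = [s.value for s in CLASSIFIABLE_SECTIONS]


def sentence_features(abstract: Abstract, index: int) -> dict[str, float]:
    """Feature dict for the ``index``-th body sentence of ``abstract``.

    Bag of lowercased tokens of the sentence plus neighbor-sentence bags
    (``prev=``/``next=`` prefixed), relative position in [0, 1], and
    first/last flags.  Deterministic.
    """
    sents = abstract.sentences
    n = len(sents)
    sent = sents[index]
    feats: dict[str, float] = {}
    for tok in sent.tokens:
        feats[f"tok={tok.text.lower()}"] = 1.0
    if index > 0:
        for tok in sents[index - 1].tokens:
            feats[f"prev={tok.text.lower()}"] = 1.0
    if index < n - 1:
        for tok in sents[index + 1].tokens:
            feats[f"next={tok.text.lower()}"] = 1.0
    feats["pos"] = index / max(1, n - 1)
    if index == 0:
        feats["is_first"] = 1.0
    if index == n - 1:
        feats["is_last"] = 1.0
    return feats


@dataclass
class ClassifierModel:
    """A trained section classifier (backend parameters are opaque)."""

    backend: str
    vectorizer: DictVectorizer
    estimator: LogisticRegression
    labels: list[str] = field(default_factory=lambda: list(_LABEL_ORDER))
    feature_spec_version: str = FEATURE_SPEC_VERSION

    def _check(self) -> None:
        if sorted(self.labels) != sorted(_LABEL_ORDER):
            raise ValueError(
                f"model label set {self.labels} != required {_LABEL_ORDER}"
            )
        if self.feature_spec_version != FEATURE_SPEC_VERSION:
            raise ValueError(
                f"feature spec mismatch: model={self.feature_spec_version} "
                f"code={FEATURE_SPEC_VERSION}"
            )

    def predict_abstract(self, abstract: Abstract) -> list[SectionLabel]:
        """Predicted section for each body sentence, in order."""
        self._check()
        if not abstract.sentences:
            return []
        X = self.vectorizer.transform(
            [sentence_features(abstract, i) for i in range(len(abstract.sentences))]
        )
        scores = self.estimator.decision_function(X)
        if scores.ndim == 1:  # binary edge case; not reachable with 4 classes
            scores = np.stack([-scores, scores], axis=1)
        # reorder columns to canonical order so argmax ties break toward
        # the earlier label in (BG, MT, RS, CC)
        col = {c: j for j, c in enumerate(self.estimator.classes_)}
        ordered = scores[:, [col[lab] for lab in _LABEL_ORDER]]
        idx = np.argmax(ordered, axis=1)
        return [SectionLabel(_LABEL_ORDER[j]) for j in idx]

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} is not a section classifier model")
        model._check()
        return model


def train_classifier(
    corpus: Corpus,
    backend: str = "linear",
    seed: int = 0,
    C: float = 10.0,
) -> ClassifierModel:
    """Train the section classifier on gold-labeled sentences.

    Every training sentence must carry a gold section label and all four
    classes must be represented.  Training is deterministic given
    ``(corpus, backend config, seed)``.
    """
    if backend != "linear":
        from .backends import train_transformer_classifier

        return train_transformer_classifier(corpus, seed=seed)

    feats: list[dict[str, float]] = []
    y: list[str] = []
    for ab in corpus:
        for i, sent in enumerate(ab.sentences):
            if sent.gold_section is None:
                raise ValueError(
                    f"{ab.doc_id}: sentence {sent.sid} has no gold section label"
                )
            feats.append(sentence_features(ab, i))
            y.append(sent.gold_section.value)
    present = set(y)
    missing = [lab for lab in _LABEL_ORDER if lab not in present]
    if missing:
        raise ValueError(f"training data lacks classes: {missing}")

    vectorizer = DictVectorizer(sparse=True)
    X = vectorizer.fit_transform(feats)
    estimator = LogisticRegression(
        C=C, max_iter=2000, solver="lbfgs", random_state=seed
    )
    estimator.fit(X, y)
    train_acc = float(estimator.score(X, y))
    logger.info("section classifier trained: %d sentences, training accuracy %.4f",
                len(y), train_acc)
    return ClassifierModel(backend="linear", vectorizer=vectorizer,
                           estimator=estimator)


def classify_abstract(
    model: ClassifierModel,
    abstract: Abstract,
    trust_headings: bool = False,
    monotone: bool = False,
) -> Abstract:
    """Fill ``pred_section`` on every body sentence (title untouched).

    With ``trust_headings`` and a structured abstract, gold heading labels
    are copied and the classifier is skipped.  With ``monotone``, a joint
    decode enforces the canonical section order BG <= MT <= RS <= CC over
    the whole abstract (sections may be skipped but never revisited).
    """
    if trust_headings and abstract.structured:
        for sent in abstract.sentences:
            if sent.gold_section is None:
                raise ValueError(
                    f"{abstract.doc_id}: --trust-headings set but sentence "
                    f"{sent.sid} has no heading-derived label"
                )
            sent.pred_section = sent.gold_section
        return abstract
    if not abstract.sentences:
        return abstract
    if monotone:
        labels = _monotone_decode(model, abstract)
    else:
        labels = model.predict_abstract(abstract)
    for sent, lab in zip(abstract.sentences, labels):
        sent.pred_section = lab
    return abstract


def _monotone_decode(model: ClassifierModel, abstract: Abstract) -> list[SectionLabel]:
    """Best label path with non-decreasing section order (Viterbi over 4 states)."""
    model._check()
    X = model.vectorizer.transform(
        [sentence_features(abstract, i) for i in range(len(abstract.sentences))]
    )
    logp = model.estimator.predict_log_proba(X)
    col = {c: j for j, c in enumerate(model.estimator.classes_)}
    logp = logp[:, [col[lab] for lab in _LABEL_ORDER]]
    n, k = logp.shape
    best = np.full((n, k), -np.inf)
    back = np.zeros((n, k), dtype=int)
    best[0] = logp[0]
    for t in range(1, n):
        for j in range(k):
            prev = best[t - 1, : j + 1]  # only same-or-earlier sections
            i = int(np.argmax(prev))
            best[t, j] = prev[i] + logp[t, j]
            back[t, j] = i
    path = [int(np.argmax(best[-1]))]
    for t in range(n - 1, 0, -1):
        path.append(back[t, path[-1]])
    path.reverse()
    return [SectionLabel(_LABEL_ORDER[j]) for j in path]


def classify_corpus(model: ClassifierModel, corpus: Corpus, **kwargs) -> Corpus:
    for ab in corpus:
        classify_abstract(model, ab, **kwargs)
    return corpus


def evaluate_classifier(model: ClassifierModel, corpus: Corpus):
    """Per-class and micro P/R/F1 of the classifier against gold sections.

    Returns an :class:`picopipe.evaluation.EvalReport` with per-class rows
    (BG, MT, RS, CC) and a micro-averaged overall row computed from summed
    TP/FP/FN.  For single-label classification micro precision, recall and
    F1 all equal accuracy.
    """
    from .evaluation import EvalReport

    if not corpus or not any(ab.sentences for ab in corpus):
        raise ValueError("cannot evaluate on an empty corpus")
    counts = {lab: [0, 0, 0] for lab in _LABEL_ORDER}  # tp, fp, fn
    for ab in corpus:
        preds = model.predict_abstract(ab)
        for sent, pred in zip(ab.sentences, preds):
            if sent.gold_section is None:
                raise ValueError(
                    f"{ab.doc_id}: sentence {sent.sid} lacks a gold section"
                )
            gold = sent.gold_section.value
            if gold == pred.value:
                counts[gold][0] += 1
            else:
                counts[pred.value][1] += 1
                counts[gold][2] += 1
    return EvalReport.from_counts(
        granularity="sentence_class",
        counts={lab: tuple(v) for lab, v in counts.items()},
        class_order=_LABEL_ORDER,
    )
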