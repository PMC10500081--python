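"""Token-level BIO tagging of PICO mentions.

The default backend is a from-scratch linear-chain structured tagger in
the same hypothesis class as a linear-chain CRF: per-token emission
features with learned weights, learned transition weights between
consecutive BIO labels, and exact Viterbi decoding.  Training uses the
averaged structured perceptron, which is fully deterministic given a seed
and needs no gradient machinery.

Invalid BIO bigrams (``O -> I-c`` and ``I-c' -> I-c`` with ``c' != c``,
plus ``I-c`` at sentence start) are *hard-masked* with minus-infinity
transition scores, so the decoder can never emit an invalid sequence and
no post-hoc repair is needed on this backend.

The sentence's section label (title vs methods etc.) is an emission
feature: Control/Intervention confusion is driven by missing context, and
the section is the cheapest context signal available to a linear model.

Score ties break by preferring ``O``, then the lexicographically earlier
label.

A transformer fine-tuning backend is an optional adapter behind the same
contract; see :mod:`picopipe.backends`.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .corpus_io import BIO_LABELS, bio_to_spans, spans_to_bio
from .types import (
    Abstract,
    Corpus,
    EntitySpan,
    SectionLabel,
    Sentence,
)

logger = logging.getLogger(__name__)

FEATURE_SPEC_VERSION = "tokfeat-v1"

N_LABELS = len(BIO_LABELS)
_LABEL_INDEX = {lab: i for i, lab in enumerate(BIO_LABELS)}

NEG_INF = -np.inf


def _transition_mask() -> tuple[np.ndarray, np.ndarray]:
    """(start mask, transition mask): 0 where allowed, -inf where forbidden."""
    start = np.zeros(N_LABELS)
    trans = np.zeros((N_LABELS, N_LABELS))
    for j, b in enumerate(BIO_LABELS):
        if b.startswith("I-"):
            start[j] = NEG_INF  # I-c cannot open a sentence
            for i, a in enumerate(BIO_LABELS):
                if a == "O" or a[2:] != b[2:]:
                    trans[i, j] = NEG_INF
    return start, trans

_START_MASK, _TRANS_MASK = _transition_mask()


def _shape(token: str) -> str:
    out = []
    for ch in token:
        if ch.isdigit():
            c = "9"
        elif ch.isupper():
            c = "X"
        elif ch.islower():
            c = "x"
        else:
            c = ch
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def token_features(sentence: Sentence, index: int,
                   section: Optional[SectionLabel] = None) -> list[str]:
    """Sparse binary features for one token.

    Lowercased identity, shape, 3/4-char prefixes and suffixes, neighbor
    identities, a numeric flag, position flags and the sentence's section
    label.  For tokens unseen in training, shape/affix features still fire.
    """
    toks = sentence.tokens
    w = toks[index].text
    lw = w.lower()
    feats = [
        "bias",
        f"w={lw}",
        f"shape={_shape(w)}",
        f"pre3={lw[:3]}",
        f"pre4={lw[:4]}",
        f"suf3={lw[-3:]}",
        f"suf4={lw[-4:]}",
    ]
    if w.replace(".", "", 1).replace(",", "").isdigit():
        feats.append("isnum")
    feats.append(f"prev={toks[index - 1].text.lower()}" if index > 0 else "prev=<s>")
    feats.append(f"next={toks[index + 1].text.lower()}"
                 if index < len(toks) - 1 else "next=</s>")
    if section is not None:
        feats.append(f"section={section.value}")
    return feats


@dataclass
class TaggerModel:
    """Linear-chain tagger: emission weights per feature + transitions.

    ``weights`` maps a feature string to a length-9 score vector over
    :data:`~picopipe.corpus_io.BIO_LABELS`; ``start``/``trans`` carry the
    transition scores with the hard BIO mask baked in as minus infinity.
    """

    backend: str = "perceptron"
    labels: tuple[str, ...] = BIO_LABELS
    weights: dict[str, np.ndarray] = field(default_factory=dict)
    start: np.ndarray = field(default_factory=lambda: _START_MASK.copy())
    trans: np.ndarray = field(default_factory=lambda: _TRANS_MASK.copy())
    feature_spec_version: str = FEATURE_SPEC_VERSION

    def _check(self) -> None:
        if tuple(self.labels) != BIO_LABELS:
            raise ValueError(f"model label inventory {self.labels} != {BIO_LABELS}")
        if self.feature_spec_version != FEATURE_SPEC_VERSION:
            raise ValueError(
                f"feature spec mismatch: model={self.feature_spec_version} "
                f"code={FEATURE_SPEC_VERSION}"
            )

    def emissions(self, sentence: Sentence,
                  section: Optional[SectionLabel]) -> np.ndarray:
        """(n_tokens, 9) emission score matrix."""
        E = np.zeros((len(sentence.tokens), N_LABELS))
        for i in range(len(sentence.tokens)):
            for f in token_features(sentence, i, section):
                vec = self.weights.get(f)
                if vec is not None:
                    E[i] += vec
        return E

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TaggerModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} is not a tagger model")
        model._check()
        return model

    def weights_digest(self) -> str:
        """Stable digest of all weights (for determinism checks)."""
        import hashlib

        h = hashlib.sha256()
        for f in sorted(self.weights):
            h.update(f.encode())
            h.update(np.ascontiguousarray(self.weights[f]).tobytes())
        h.update(np.ascontiguousarray(self.start).tobytes())
        h.update(np.ascontiguousarray(self.trans).tobytes())
        return h.hexdigest()


def viterbi_path(emissions: np.ndarray, start: np.ndarray,
                 trans: np.ndarray) -> list[int]:
    """Exact argmax label path under emission + transition scores.

    Ties break toward the lower label index; with the canonical label
    order that means preferring ``O``, then the lexicographically earlier
    label.  Strict ``>`` comparisons implement the tie-break.
    """
    n = emissions.shape[0]
    if n == 0:
        return []
    k = emissions.shape[1]
    delta = start + emissions[0]
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + trans  # cand[i, j]: best-through-i to j
        best_prev = np.argmax(cand, axis=0)  # np.argmax: first max wins ties
        delta = cand[best_prev, np.arange(k)] + emissions[t]
        back[t] = best_prev
    path = [int(np.argmax(delta))]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path


def viterbi_decode(model: TaggerModel, sentence: Sentence,
                   section: Optional[SectionLabel] = None) -> list[str]:
    """Decode one sentence to a valid BIO tag sequence."""
    if not sentence.tokens:
        return []
    E = model.emissions(sentence, section)
    path = viterbi_path(E, model.start, model.trans)
    return [BIO_LABELS[j] for j in path]


# ---------------------------------------------------------------------------
# Training: averaged structured perceptron
# ---------------------------------------------------------------------------


def _training_sentences(
    corpus: Corpus, sections: Iterable[SectionLabel]
) -> list[tuple[str, Sentence, SectionLabel, list[str]]]:
    wanted = set(sections)
    out = []
    for ab in corpus:
        by_sid: dict[int, list[EntitySpan]] = {}
        for span in ab.entities:
            by_sid.setdefault(span.sid, []).append(span)
        for sent in ab.all_sentences():
            sec = sent.gold_section
            if sec is None or sec not in wanted:
                continue
            try:
                tags = spans_to_bio(sent, by_sid.get(sent.sid, []))
            except ValueError as exc:
                raise ValueError(f"{ab.doc_id} sid={sent.sid}: {exc}") from exc
            out.append((ab.doc_id, sent, sec, tags))
    return out


DEFAULT_TRAIN_SECTIONS = (SectionLabel.TITLE, SectionLabel.METHODS)


def train_tagger(
    corpus: Corpus,
    backend: str = "perceptron",
    seed: int = 0,
    epochs: int = 10,
    sections: Sequence[SectionLabel] = DEFAULT_TRAIN_SECTIONS,
) -> TaggerModel:
    """Train the linear-chain tagger with the averaged perceptron.

    Only sentences whose gold section is in ``sections`` (default: title +
    methods, matching the annotation schema) contribute.  Deterministic
    given ``(corpus, epochs, seed)``; per-epoch training mistakes are
    logged.  A corpus with no entity spans trains to an all-O model with a
    warning.
    """
    if backend != "perceptron":
        from .backends import train_transformer_tagger

        return train_transformer_tagger(corpus, seed=seed)

    data = _training_sentences(corpus, sections)
    if not any(tag != "O" for _, _, _, tags in data for tag in tags):
        logger.warning("training corpus contains no entity spans; "
                       "model will predict all O")

    model = TaggerModel()
    weights = model.weights
    # averaged perceptron with lazy accumulators
    totals: dict[str, np.ndarray] = {}
    stamps: dict[str, int] = {}
    t_start = np.zeros(N_LABELS)
    t_trans = np.zeros((N_LABELS, N_LABELS))
    t_start_total = np.zeros(N_LABELS)
    t_trans_total = np.zeros((N_LABELS, N_LABELS))
    trans_stamp = 0
    step = 0
    rng = np.random.default_rng(seed)
    order = np.arange(len(data))

    feature_cache = [
        [token_features(sent, i, sec) for i in range(len(sent.tokens))]
        for _, sent, sec, _ in data
    ]

    def bump(f: str, j: int, delta: float) -> None:
        vec = weights.get(f)
        if vec is None:
            vec = np.zeros(N_LABELS)
            weights[f] = vec
            totals[f] = np.zeros(N_LABELS)
            stamps[f] = step
        else:
            totals[f] += (step - stamps[f]) * vec
            stamps[f] = step
        vec[j] += delta

    for epoch in range(epochs):
        rng.shuffle(order)
        mistakes = 0
        for di in order:
            _, sent, sec, gold = data[di]
            feats = feature_cache[di]
            if not sent.tokens:
                continue
            # the averaging clock ticks per instance, not per update, so
            # weights that survive unchallenged gain proportional mass
            step += 1
            E = np.zeros((len(sent.tokens), N_LABELS))
            for i, fs in enumerate(feats):
                for f in fs:
                    vec = weights.get(f)
                    if vec is not None:
                        E[i] += vec
            pred_idx = viterbi_path(E, model.start + t_start,
                                    model.trans + t_trans)
            gold_idx = [_LABEL_INDEX[g] for g in gold]
            if pred_idx == gold_idx:
                continue
            mistakes += 1
            for i, fs in enumerate(feats):
                g, p = gold_idx[i], pred_idx[i]
                if g == p:
                    continue
                for f in fs:
                    bump(f, g, +1.0)
                    bump(f, p, -1.0)
            # transition updates (start + bigrams), with lazy averaging
            t_start_total += (step - trans_stamp) * t_start
            t_trans_total += (step - trans_stamp) * t_trans
            trans_stamp = step
            t_start[gold_idx[0]] += 1
            t_start[pred_idx[0]] -= 1
            for a, b in zip(gold_idx, gold_idx[1:]):
                t_trans[a, b] += 1
            for a, b in zip(pred_idx, pred_idx[1:]):
                t_trans[a, b] -= 1
        logger.info("tagger epoch %d: %d/%d sentences updated",
                    epoch + 1, mistakes, len(data))

    # finalize averaged weights (the hard mask stays -inf regardless)
    final_step = max(step, 1)
    for f, vec in weights.items():
        totals[f] += (step - stamps[f]) * vec
        weights[f] = totals[f] / final_step if step > 0 else vec
    t_start_total += (step - trans_stamp) * t_start
    t_trans_total += (step - trans_stamp) * t_trans
    avg_start = t_start_total / final_step if step > 0 else t_start
    avg_trans = t_trans_total / final_step if step > 0 else t_trans
    model.start = model.start + avg_start
    model.trans = model.trans + avg_trans
    model.weights = weights
    return model


def tag_sentence(model: TaggerModel, sentence: Sentence,
                 section: Optional[SectionLabel] = None) -> list[EntitySpan]:
    tags = viterbi_decode(model, sentence, section)
    return bio_to_spans(sentence, tags)


def tag_corpus(
    model: TaggerModel,
    corpus: Corpus,
    sections_to_tag: Iterable[SectionLabel] = (SectionLabel.METHODS,),
    use_sections: str = "gold",
) -> Corpus:
    """Attach predicted spans to selected sentences of every abstract.

    The title pseudo-sentence is always decoded; body sentences are decoded
    iff their effective section (gold or predicted, per ``use_sections``)
    is in ``sections_to_tag``.  Raises if a needed section label is absent.
    """
    wanted = set(sections_to_tag)
    for ab in corpus:
        preds: list[EntitySpan] = []
        for sent in ab.all_sentences():
            if sent.is_title:
                sec: Optional[SectionLabel] = SectionLabel.TITLE
            else:
                sec = sent.effective_section(prefer=use_sections)
                if sec is None:
                    raise ValueError(
                        f"{ab.doc_id}: sentence {sent.sid} has no "
                        f"{use_sections} section label; run the classifier "
                        "first or pass use_sections='gold'"
                    )
                if sec not in wanted:
                    continue
            preds.extend(tag_sentence(model, sent, sec))
        ab.pred_entities = preds
    return corpus
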