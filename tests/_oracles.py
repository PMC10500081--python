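"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration and
per-token tallies — so it stays independent of the implementation paths
it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from picopipe.corpus_io import BIO_LABELS, tokenize
from picopipe.types import EntityClass, EntitySpan, Sentence


def brute_force_best_path_score(emissions: np.ndarray, start: np.ndarray,
                                trans: np.ndarray) -> float:
    """Max path score over ALL label sequences, scored vectorized.

    Invalid transitions carry -inf in ``start``/``trans`` and eliminate
    themselves.
    """
    n, k = emissions.shape
    paths = np.array(list(itertools.product(range(k), repeat=n)), dtype=np.int64)
    scores = start[paths[:, 0]] + emissions[0, paths[:, 0]]
    for t in range(1, n):
        scores = scores + trans[paths[:, t - 1], paths[:, t]] + emissions[t, paths[:, t]]
    return float(np.max(scores))


def path_score(path: list[int], emissions: np.ndarray, start: np.ndarray,
               trans: np.ndarray) -> float:
    s = start[path[0]] + emissions[0, path[0]]
    for t in range(1, len(path)):
        s += trans[path[t - 1], path[t]] + emissions[t, path[t]]
    return float(s)


def brute_force_token_counts(gold: list[str], pred: list[str]) -> dict[str, tuple[int, int, int]]:
    """Per-class (TP, FP, FN) by looping classes over tokens.

    Outside ('OUT') is never a counted class, so Outside/Outside agreement
    contributes nothing by construction.
    """
    out = {}
    for cls in "PICO":
        tp = sum(1 for g, p in zip(gold, pred) if g == cls and p == cls)
        fp = sum(1 for g, p in zip(gold, pred) if p == cls and g != cls)
        fn = sum(1 for g, p in zip(gold, pred) if g == cls and p != cls)
        out[cls] = (tp, fp, fn)
    return out


def brute_force_exact_counts(gold: list[EntitySpan], pred: list[EntitySpan]
                             ) -> tuple[int, int, int]:
    gset = {(s.sid, s.start, s.end, s.cls) for s in gold}
    pset = {(s.sid, s.start, s.end, s.cls) for s in pred}
    tp = len(gset & pset)
    return tp, len(pset) - tp, len(gset) - tp


def brute_force_optimal_matching(gold: list[EntitySpan], pred: list[EntitySpan],
                                 token_range) -> int:
    """Max cardinality of a one-to-one same-class >=1-token-overlap matching.

    Exhaustive over injections of gold spans into predicted spans; only
    usable for tiny span sets.
    """
    def compatible(g: EntitySpan, p: EntitySpan) -> bool:
        if g.sid != p.sid or g.cls != p.cls:
            return False
        gs, ge = token_range(g)
        ps, pe = token_range(p)
        return min(ge, pe) - max(gs, ps) >= 1

    best = 0
    n_p = len(pred)
    for subset_size in range(min(len(gold), n_p), best, -1):
        for g_subset in itertools.combinations(range(len(gold)), subset_size):
            for p_perm in itertools.permutations(range(n_p), subset_size):
                if all(compatible(gold[g], pred[p]) for g, p in zip(g_subset, p_perm)):
                    return subset_size
    return 0


_VOCAB = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta"]


def random_annotated_sentence(rng: np.random.Generator, sid: int = 0,
                              max_tokens: int = 10, allow_empty: bool = True
                              ) -> tuple[Sentence, list[EntitySpan]]:
    """A random sentence with random token-aligned non-overlapping spans."""
    n = int(rng.integers(0 if allow_empty else 1, max_tokens + 1))
    words = [str(rng.choice(_VOCAB)) for _ in range(n)]
    text = " ".join(words)
    sent = Sentence(sid=sid, text=text, tokens=tokenize(text))
    spans: list[EntitySpan] = []
    i = 0
    classes = list(EntityClass)
    while i < n:
        if rng.random() < 0.4:
            length = int(rng.integers(1, min(3, n - i) + 1))
            cls = classes[int(rng.integers(0, 4))]
            start = sent.tokens[i].start
            end = sent.tokens[i + length - 1].end
            spans.append(EntitySpan(sid=sid, start=start, end=end, cls=cls,
                                    text=text[start:end]))
            i += length
        else:
            i += 1
    return sent, spans


def random_valid_bio(rng: np.random.Generator, n: int) -> list[str]:
    """A uniformly grown valid BIO sequence of length n."""
    tags: list[str] = []
    prev = "O"
    for _ in range(n):
        options = ["O", "B-P", "B-I", "B-C", "B-O"]
        if prev != "O":
            options.append("I-" + prev[2:])
        tag = options[int(rng.integers(0, len(options)))]
        tags.append(tag)
        prev = tag
    return tags


def random_tag_pair(rng: np.random.Generator, n: int) -> tuple[list[str], list[str]]:
    """Aligned random collapsed-label sequences ('OUT' marks Outside)."""

    def draw() -> list[str]:
        out = []
        for _ in range(n):
            if rng.random() < 0.5:
                out.append("OUT")
            else:
                out.append("PICO"[int(rng.integers(0, 4))])
        return out

    return draw(), draw()
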