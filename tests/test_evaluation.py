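"""Metric definitions: token-level, entity-level, kappa, confusion, CV."""

import numpy as np
import pytest

from picopipe.evaluation import (
    EvalReport,
    cohens_kappa,
    confusion,
    entity_eval,
    greedy_partial_match,
    kappa_from_labels,
    kfold_split,
    token_counts,
    token_eval,
)
from picopipe.types import Abstract, EntityClass, EntitySpan, SectionLabel

from _oracles import (
    brute_force_exact_counts,
    brute_force_optimal_matching,
    brute_force_token_counts,
    random_annotated_sentence,
    random_tag_pair,
)
from conftest import make_sentence


# ---------------------------------------------------------------------------
# The worked participant example
# ---------------------------------------------------------------------------

def test_worked_example_token_level(covid_example):
    """Gold [P,P,P,P] vs pred [P,P,O,P]: TP=3, FN=1, FP=0 -> P=1.0, R=0.75."""
    report = token_eval([covid_example])
    p = report.per_class["P"]
    assert (p.tp, p.fp, p.fn) == (3, 0, 1)
    assert p.precision == 1.0
    assert p.recall == 0.75


def test_worked_example_entity_exact(covid_example):
    report = entity_eval([covid_example], mode="exact")
    p = report.per_class["P"]
    assert (p.tp, p.fp, p.fn) == (0, 2, 1)


def test_worked_example_entity_partial(covid_example):
    """The longer overlap ('86 hospitalized') matches; 'patients' is FP."""
    report = entity_eval([covid_example], mode="partial")
    p = report.per_class["P"]
    assert (p.tp, p.fp, p.fn) == (1, 1, 0)


# ---------------------------------------------------------------------------
# Token-level counting vs brute force; Outside excluded
# ---------------------------------------------------------------------------

def test_identical_annotations_score_one(covid_example):
    ab = Abstract(doc_id="d", title=covid_example.title,
                  sentences=covid_example.sentences,
                  entities=list(covid_example.entities),
                  pred_entities=list(covid_example.entities))
    for rep in (token_eval([ab]), entity_eval([ab], mode="exact"),
                entity_eval([ab], mode="partial")):
        assert rep.micro.f1 == 1.0


def test_outside_agreement_contributes_nothing():
    counts = token_counts(["OUT", "OUT", "P"], ["OUT", "OUT", "P"])
    assert counts["P"] == [1, 0, 0]
    assert all(counts[c] == [0, 0, 0] for c in "ICO")


def test_token_counts_match_brute_force_oracle():
    rng = np.random.default_rng(21)
    for _ in range(500):
        g, p = random_tag_pair(rng, int(rng.integers(1, 15)))
        ours = {c: tuple(v) for c, v in token_counts(g, p).items()}
        assert ours == brute_force_token_counts(g, p)


def test_micro_from_summed_counts_not_macro_average():
    # asymmetric case: P has many errors, I is perfect
    report = EvalReport.from_counts("token", {
        "P": (1, 9, 9), "I": (10, 0, 0), "C": (0, 0, 0), "O": (0, 0, 0),
    })
    micro = report.micro
    assert micro.precision == 11 / 20
    assert micro.recall == 11 / 20
    assert report.macro_f1 != pytest.approx(micro.f1)
    # 0/0 convention
    assert report.per_class["C"].f1 == 0.0


# ---------------------------------------------------------------------------
# Entity-level: exact vs partial, greedy vs optimal matching
# ---------------------------------------------------------------------------

def _random_eval_case(rng):
    sent, gold = random_annotated_sentence(rng, sid=0, max_tokens=8,
                                           allow_empty=False)
    _, pred = random_annotated_sentence(rng, sid=0, max_tokens=8)
    # regenerate pred spans on the SAME sentence so offsets align
    pred = []
    i = 0
    n = len(sent.tokens)
    while i < n:
        if rng.random() < 0.4:
            length = int(rng.integers(1, min(3, n - i) + 1))
            cls = list(EntityClass)[int(rng.integers(0, 4))]
            start, end = sent.tokens[i].start, sent.tokens[i + length - 1].end
            pred.append(EntitySpan(sid=0, start=start, end=end, cls=cls,
                                   text=sent.text[start:end]))
            i += length
        else:
            i += 1
    ab = Abstract(doc_id="d", title="T", sentences=[sent], entities=gold,
                  pred_entities=pred)
    return ab, sent, gold, pred


def test_exact_counts_match_set_oracle_and_partial_dominates():
    rng = np.random.default_rng(77)
    greedy_optimal_agree = 0
    n_cases = 500
    for _ in range(n_cases):
        ab, sent, gold, pred = _random_eval_case(rng)
        exact = entity_eval([ab], mode="exact")
        tp, fp, fn = brute_force_exact_counts(gold, pred)
        assert (exact.micro.tp, exact.micro.fp, exact.micro.fn) == (tp, fp, fn)

        partial = entity_eval([ab], mode="partial")
        # monotonicity: every exact match is also a partial match
        assert exact.micro.tp <= partial.micro.tp

        if len(gold) <= 6 and len(pred) <= 6:
            def token_range(sp):
                first = next(i for i, t in enumerate(sent.tokens)
                             if t.start == sp.start)
                last = next(i for i, t in enumerate(sent.tokens)
                            if t.end == sp.end)
                return first, last + 1

            optimal = brute_force_optimal_matching(gold, pred, token_range)
            assert partial.micro.tp <= optimal
            if partial.micro.tp == optimal:
                greedy_optimal_agree += 1
        else:
            greedy_optimal_agree += 1
    # greedy equals the optimal assignment on >= 95% of random cases
    assert greedy_optimal_agree / n_cases >= 0.95


def test_partial_match_is_one_to_one():
    sent = make_sentence("alpha beta gamma delta epsilon")
    gold = [EntitySpan(0, 0, 16, EntityClass.P, sent.text[0:16])]  # 3 tokens
    pred = [EntitySpan(0, 0, 10, EntityClass.P, sent.text[0:10]),
            EntitySpan(0, 11, 16, EntityClass.P, sent.text[11:16])]
    pairs = greedy_partial_match(gold, pred, lambda sid: sent)
    assert len(pairs) == 1
    assert pairs[0][1].end == 10  # longest overlap (2 tokens) wins


def test_partial_requires_same_class():
    sent = make_sentence("alpha beta")
    gold = [EntitySpan(0, 0, 10, EntityClass.P, sent.text)]
    pred = [EntitySpan(0, 0, 10, EntityClass.I, sent.text)]
    pairs = greedy_partial_match(gold, pred, lambda sid: sent)
    assert pairs == []


def test_metrics_invariant_under_document_reordering():
    rng = np.random.default_rng(3)
    corpus = [
        _random_eval_case(rng)[0] for _ in range(6)
    ]
    for i, ab in enumerate(corpus):
        ab.doc_id = f"d{i}"
    fwd = token_eval(corpus).to_dict()
    rev = token_eval(list(reversed(corpus))).to_dict()
    assert fwd == rev
    assert entity_eval(corpus, mode="partial").to_dict() == \
        entity_eval(list(reversed(corpus)), mode="partial").to_dict()


# ---------------------------------------------------------------------------
# Confusion matrix
# ---------------------------------------------------------------------------

def test_confusion_perfect_is_diagonal(covid_example):
    ab = Abstract(doc_id="d", title="T", sentences=covid_example.sentences,
                  entities=list(covid_example.entities),
                  pred_entities=list(covid_example.entities))
    M = confusion([ab])
    off_diag = M.counts - np.diag(np.diag(M.counts))
    assert off_diag.sum() == 0


def test_confusion_all_o_prediction(covid_example):
    ab = Abstract(doc_id="d", title="T", sentences=covid_example.sentences,
                  entities=list(covid_example.entities), pred_entities=[])
    M = confusion([ab])
    out_col = M.labels.index("OUT")
    assert M.counts.sum() == M.counts[:, out_col].sum()


def test_confusion_hand_counted():
    sent = make_sentence("a b c d e f g h i j")
    gold = [EntitySpan(0, 0, 3, EntityClass.P, "a b"),      # tokens 0-1
            EntitySpan(0, 4, 7, EntityClass.I, "c d")]      # tokens 2-3
    pred = [EntitySpan(0, 0, 1, EntityClass.P, "a"),        # token 0
            EntitySpan(0, 2, 5, EntityClass.C, "b c"),      # tokens 1-2
            EntitySpan(0, 8, 9, EntityClass.O, "e")]        # token 4
    ab = Abstract(doc_id="d", title="T", sentences=[sent], entities=gold,
                  pred_entities=pred)
    M = confusion([ab])
    idx = {lab: i for i, lab in enumerate(M.labels)}
    # gold row P: token0 -> P, token1 -> C
    assert M.counts[idx["P"], idx["P"]] == 1
    assert M.counts[idx["P"], idx["C"]] == 1
    # gold row I: token2 -> C, token3 -> Outside
    assert M.counts[idx["I"], idx["C"]] == 1
    assert M.counts[idx["I"], idx["OUT"]] == 1
    # Outside row: token4 -> Outcome class; tokens 5-9 and the one-token
    # title stay Outside/Outside
    assert M.counts[idx["OUT"], idx["O"]] == 1
    assert M.counts[idx["OUT"], idx["OUT"]] == 6
    # every token of the document lands in exactly one cell
    assert M.counts.sum() == 11
    # row-normalized view sums to 1 on non-empty rows
    norm = M.normalized()
    assert norm[idx["P"]].sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

def test_kappa_identical_annotations():
    labels = ["P", "O", "I", "O", "C"] * 4
    res = kappa_from_labels(labels, labels)
    assert res.kappa == 1.0 and res.p_o == 1.0


def test_kappa_constructed_po_pe():
    """20 tokens, marginals 10/10 each side, 16 agreements:
    p_o = 0.8, p_e = 0.5, kappa = 0.6 exactly."""
    a = ["P"] * 10 + ["O"] * 10
    b = ["P"] * 8 + ["O"] * 2 + ["P"] * 2 + ["O"] * 8
    res = kappa_from_labels(a, b)
    assert res.p_o == pytest.approx(0.8)
    assert res.p_e == pytest.approx(0.5)
    assert res.kappa == pytest.approx(0.6)


def test_kappa_all_o_vs_uniform_not_positive():
    a = ["O"] * 20
    b = (["P", "I", "C", "O"] * 5)
    res = kappa_from_labels(a, b)
    assert res.kappa <= 0


def test_kappa_corpus_level_and_per_class(covid_example):
    other = Abstract(doc_id="covid-example", title=covid_example.title,
                     sentences=covid_example.sentences,
                     entities=list(covid_example.entities))
    res = cohens_kappa([covid_example], [other])
    assert res.kappa == 1.0
    res_p = cohens_kappa([covid_example], [other], basis="P")
    assert res_p.kappa == 1.0
    with pytest.raises(ValueError, match="zero tokens|different"):
        kappa_from_labels([], [])


# ---------------------------------------------------------------------------
# Cross-validation splitting
# ---------------------------------------------------------------------------

def test_kfold_partition(separable_corpus):
    corpus = separable_corpus[:10]
    folds = kfold_split(corpus, k=5, seed=0)
    assert len(folds) == 5
    all_test = [ab.doc_id for _, test in folds for ab in test]
    assert sorted(all_test) == sorted(ab.doc_id for ab in corpus)
    assert len(set(all_test)) == len(all_test)  # no doc in two test folds
    for train, test in folds:
        assert len(test) == 2
        assert not ({a.doc_id for a in train} & {a.doc_id for a in test})


def test_kfold_deterministic_and_errors(separable_corpus):
    corpus = separable_corpus[:10]
    f1 = kfold_split(corpus, k=5, seed=3)
    f2 = kfold_split(corpus, k=5, seed=3)
    assert [[ab.doc_id for ab in test] for _, test in f1] == \
        [[ab.doc_id for ab in test] for _, test in f2]
    with pytest.raises(ValueError):
        kfold_split(corpus, k=11)
    with pytest.raises(ValueError):
        kfold_split(corpus, k=1)
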