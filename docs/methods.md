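# Methods

## The extraction model

PICO extraction is decomposed into two supervised steps run in sequence:

1. **Sentence section classification.** Every body sentence of an
   abstract receives one label from {background, methods, results,
   conclusions}. The *title* is handled structurally: it is modeled as a
   pseudo-sentence with reserved id −1 and the fixed label `title`, and
   never passes through the classifier. The `objective` category used by
   some structured-abstract heading schemes is folded into `background`
   at normalization time, because objective and background sentences are
   lexically close to the point that separating them adds noise without
   adding value downstream.

2. **Section-filtered NER.** P/I/C/O mentions are tagged, as flat
   non-overlapping character-offset spans, only in the title and in
   sentences labeled `methods`. The restriction is justified by the
   empirical distribution of PICO mentions in RCT abstracts: the methods
   section alone contains ~95% of a document set's unique mentions and
   title+methods >96%, while results/conclusions mostly repeat mentions
   stated in methods. The `coverage` module computes this statistic for
   any annotated corpus, so the filtering assumption is checkable rather
   than baked in; `sections_to_tag` is a parameter everywhere.

End-to-end errors compose in one direction only: a methods sentence
misrouted by the classifier loses its gold spans (false negatives), and a
non-methods sentence routed in can contribute spurious spans (false
positives). The end-to-end evaluation therefore scores the same metric
definitions over *all* sentences and never conditions on the routing.

## Default backends

Both steps are backend contracts. The defaults are deliberately
linear-model, CPU-only, and deterministic; transformer fine-tuning
adapters exist behind the same contracts (`picopipe.backends`) with their
hyperparameter presets recorded, but require the optional
`picopipe[transformer]` dependencies and are not used by any test.

**Classifier.** Multinomial logistic regression (L2, C=10, lbfgs) over
sparse binary features: bag of lowercased tokens of the sentence, the
previous-sentence and next-sentence bags under `prev=`/`next=` prefixes,
relative position in [0,1], and first/last flags. Neighbor bags are the
desk-scale stand-in for the context-sensitivity that sequential sentence
classifiers get from recurrent or attention context. Ties in predicted
scores break toward the earlier label in the fixed order (background,
methods, results, conclusions). An optional joint decode
(`monotone=True`) enforces the canonical non-decreasing section order
over the abstract via a 4-state Viterbi pass on per-sentence
log-probabilities; it is off by default because single-sentence
classification is the primary contract and the monotone prior, while
true of well-formed structured abstracts, is not guaranteed for
free-text ones.

**Tagger.** A linear-chain structured model over the 9-label BIO
inventory (O + B/I × 4 classes): emission weights over per-token features
(lowercased identity, character shape, 3/4-char prefixes/suffixes,
neighbor identities, numeric flag, and the sentence's section label) plus
a learned transition matrix. Invalid BIO bigrams — `I-c` after `O`,
after a different class, or at sentence start — are hard-masked with
−∞ transition scores, so the decoder cannot emit an invalid sequence
and no repair is ever needed on this backend. (The conservative-begin
repair, stranded `I-c` → `B-c`, still exists in `corpus_io` for
backends that predict token labels independently.) The section label as
an emission feature is the cheapest form of the "more context" remedy
for Control/Intervention confusion: the same drug phrase is Intervention
or Control depending on which arm the sentence describes, and a linear
emission model cannot see that from the token alone.

Training is the averaged structured perceptron: decode with current
weights, and on a mistake add the gold feature vector and subtract the
predicted one, for emissions, start scores and transitions alike.
Averaging uses the standard lazy accumulators with a clock that ticks
once per training *instance* (not per update), so weights that survive
many instances unchallenged dominate the average — getting this clock
wrong silently costs ~0.12 held-out F1, which is why the determinism
test pins the weight digest and the learning tests pin held-out
performance. Instance order is shuffled per epoch with a seeded
generator; everything is deterministic given (corpus, epochs, seed).
Default 10 epochs. The same hypothesis class as a linear-chain CRF is
covered; a CRF likelihood objective could be added behind the same
contract without touching the decoder or any caller.

Decoding ties break by preferring `O`, then the lexicographically
earlier label, implemented by strict-inequality argmax over the fixed
label order — so an untrained (all-zero) model decodes everything to
`O` by construction rather than by accident.

## Evaluation conventions

* **Token level**: `B-`/`I-` prefixes are collapsed to the entity class;
  tokens where both gold and prediction are Outside contribute nothing
  (scores describe entity tokens only). Internally the collapsed Outside
  symbol is `OUT`, keeping it distinct from the Outcome class `O`.
* **Entity level, exact**: a predicted span counts iff (sentence, start,
  end, class) all match a gold span.
* **Entity level, partial**: same-class spans sharing ≥1 token are
  candidate matches; matching is one-to-one, greedy by longest token
  overlap, ties by earlier gold start then earlier predicted start. The
  greedy matcher is deterministic and simple to state; the test suite
  carries an exhaustive optimal-assignment oracle and verifies that
  greedy attains the optimum on ≥95% of random flat span sets and never
  exceeds it. (On flat same-sentence spans the two rarely differ at
  all.)
* **Micro averages** are always recomputed from summed TP/FP/FN across
  classes, never by averaging per-class scores; with single-label
  sentence classification this makes micro P = micro R = accuracy. The
  macro mean is exposed separately and only for contrast.
* **0/0 = 0** for precision, recall and F1.
* **Cohen's κ** is computed token-level over class labels with Outside
  included by default; a per-class basis binarizes to class-vs-rest.
  κ = (p_o − p_e)/(1 − p_e) with p_e from the two annotators' label
  marginals; the degenerate p_e = 1 case (both annotators constant and
  identical) is defined as κ = 1.
* **Cross-validation** splits by *document*, never by sentence, to avoid
  leakage between a document's sentences; the CV summary is the mean of
  fold-level micro scores.

## Coverage analysis

For an annotated document set, the unique mentions of each class are the
per-document deduplicated normalized strings (casefold + whitespace
collapse — the same policy as `PicoRecord`), aggregated over documents.
A unique mention "appears" in a section when its normalized string occurs
anywhere in that section's sentence text, so repeats outside the
annotated sections are found by string search rather than requiring
annotation there. Coverage of section *s* is Σ_c counts[c][s] / Σ_c
totals[c], reported half-up to 3 decimals.

Applying the formula to the published per-section counts of the
30-abstract reference sample reproduces four of the five printed
coverage cells exactly (0.483, 0.435, 0.952, 0.503); the results column
computes 117/147 = 0.796 against a printed 0.800, which we treat as a
rounding or transcription slip in the source table — the implementation
reports the value the formula gives. The title+methods *union* coverage
(>96%) needs mention-level union counts that a per-section table does
not contain; `coverage_from_corpus` computes it directly from a corpus
when asked with a combined section selection.

## The synthetic corpus

The generator targets the statistical structure that makes the two-step
design work, not linguistic realism: four sections in canonical order
with section-specific filler vocabulary; a title always carrying one P
and one I phrase; methods sentences built from templates that embed P
("⟨N⟩ patients with ⟨condition⟩"), I ("⟨drug⟩ ⟨dose⟩ mg"), C (placebo
variants at configurable frequency, else active-comparator phrases) and
O ("⟨measure⟩ score") spans; and, with probability
`cross_section_repeat_prob` per phrase, verbatim *unannotated* copies of
methods entity phrases in results sentences — the duplication that makes
whole-abstract annotation ambiguous in real corpora, and the reason
coverage of results is high while its annotations would be redundant.
Cohort sizes (3-digit) and doses (2-digit) are drawn from disjoint
ranges so every number token belongs to exactly one class lexicon.

Each document consumes its own random stream keyed by (seed, document
index), so corpora are bit-reproducible and a prefix of a larger corpus
equals the smaller corpus at the same seed. `label_noise` flips the
stated fraction of gold section labels *after* generation and exists for
robustness experiments only; it is 0 by default.

The *separable* variant forces zero overlap between section
vocabularies (and entity lexicons are always disjoint from filler), so
a consistent learner can reach near-perfect accuracy; this is the
parameter-recovery harness. Passing on it demonstrates that the
learners and the pipeline plumbing are correct — it says nothing about
absolute performance on real abstracts, where vocabularies overlap
heavily, entity boundaries are genuinely ambiguous, and annotation
disagreement is part of the signal. Scores published for real corpora
are correspondingly much lower than the near-1.0 values the separable
corpus yields, and reproducing them would require those corpora and
transformer fine-tuning, both out of scope here.

For the noise-robustness check (end-to-end ≤ standalone), noise is
injected into the *classifier's training labels* while evaluation uses a
clean corpus. Flipping the evaluation corpus's own gold sections instead
would invert the comparison, because entities are planted relative to
the true sections: a correct classifier would then beat the corrupted
"gold" routing.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by choice: 60-document
corpora for unit tests, 200 documents (150 train / 50 held-out) for
parameter recovery, 200 random ≤6-token instances for decoder-optimality
enumeration, 1000 random annotations for the BIO round-trip, 500 random
cases for the metric oracles. At these sizes the whole suite runs in
well under a minute of training time because both backends are linear
models; the separable construction makes the expected outcomes sharp, so
larger sizes would add runtime without adding discrimination.

Other numerical choices: character offsets are 0-based half-open
everywhere; tokenization splits on whitespace and peels edge punctuation
(hyphens are never split, keeping "COVID-19" whole); the sentence
splitter is rule-based (`.?!` + following capital/digit, abbreviation
list) because exact segmentation is not the object of study — token
counts on externally segmented corpora are therefore not comparable
across toolchains and are not asserted anywhere.

## Known limitations

* The default backends are linear; no claim is made that they approach
  transformer performance on real abstracts. They exist to make the
  pipeline, metrics and contracts fully testable without GPUs or
  downloads.
* Mention deduplication is exact-string after normalization; lexical
  variants, abbreviations and coreference ("the program") are not
  merged.
* The annotation schema is flat: nested or overlapping gold spans are
  rejected at load.
* The PubMed-XML reader covers the minimal ArticleTitle/AbstractText
  subset, not the full DTD; full-text articles are out of scope.
* The greedy partial matcher can in principle score below the optimal
  assignment on adversarial span sets (documented property, bounded by
  the oracle test); it never scores above it.
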