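# Methods

## The extraction problem

Radiology reports are free text, but most of their clinical content fits
a small information model: *observations* (directly seen imaging
features — "nodule", "pleural effusion"), *clinical findings*
(interpretations derived from observations — "lung cancer"), and five
kinds of *modifier* attached to a concept: anatomical location,
certainty, change, characteristics and size.  Two directed relation
types connect entities: a **modifier** relation from an observation or
clinical finding to one of its modifiers, and an **evidence** relation
from an observation to the clinical finding it supports.  Structuring a
report means recovering this graph from its text.

`radstruct` implements the standard two-stage decomposition:

1. **Entity extraction** — per-sentence sequence labeling over IOB2
   tags (15 tags: `O` plus `B-`/`I-` for each of the 7 types) with a
   BiLSTM-CRF: token embeddings → bidirectional LSTM → per-tag emission
   scores → linear-chain CRF with learned transition, start and end
   scores.  Training maximizes the CRF log-likelihood (forward
   algorithm in log space); decoding is Viterbi, followed by IOB2
   repair (an orphan `I-t` after `O` or after another type is promoted
   to `B-t`).
2. **Relation extraction** — the sentences of a report are concatenated
   in order so cross-sentence relations are representable; every
   schema-admissible entity pair becomes a binary *candidate*
   (modifier: each concept × each modifier entity; evidence: each
   observation × each clinical finding).  A candidate is rendered as
   the report token sequence with four typed *entity span tokens*
   inserted around head and tail, e.g.
   `a 3 cm <OBS> nodule </OBS> in the <AE> right upper lobe </AE>`,
   and scored by a BiLSTM whose hidden states are pooled by additive
   attention (weights are a distribution over positions) into a single
   vector, then passed through `tanh` and a logistic output.
   Candidates with probability ≥ the decision threshold (default 0.5)
   become relations.

The pipeline mirrors the cascade used in practice: stage 2 consumes
stage 1's output, so entity errors propagate and the end-to-end
("pipeline") relation F1 is bounded in expectation by the F1 obtained
with gold entities.

All tensor computation is implemented directly in NumPy with explicit
forward/backward passes; the backward passes are verified against
numerical differentiation and the CRF against brute-force path
enumeration in the test suite.

## Training procedure and hyperparameters

Both models train with minibatch SGD with classical momentum and
gradient clipping by global L2 norm, and decay-on-plateau of the
learning rate monitored on the development score (entity micro-F1 for
the tagger, relation micro-F1 on gold entities for the classifier).
The checkpoint with the best development score is returned.

| parameter | default | notes |
|---|---|---|
| embedding dim | 100 | word2vec-text files can initialize matching rows |
| hidden dim | 512 | per direction; benchmarks use 128 or less |
| batch size | 16 | batches group sentences/candidates of similar length |
| dropout | 0.1 | inverted dropout on the BiLSTM input and output vectors |
| initial lr | 0.1 | SGD + momentum 0.9 |
| gradient clip | 5.0 | global L2 norm |
| lr decay | ×0.5, patience 3 | floor 1e-4 |
| unknown-token dropout | 0.01 | NER only; trains the `<unk>` embedding |
| relation window | 256 tokens | truncation centered between the pair |
| decision threshold | 0.5 | fixed, not tuned on dev |

Choices the optimization recipe leaves open were fixed as follows:
LSTM input weights use uniform Glorot initialization and the recurrent
weights per-gate orthogonal initialization (markedly faster escape from
the predict-the-class-prior plateau on the relation task); the forget
gate bias starts at 1; the relation model's output bias starts at the
log-odds of the positive-candidate rate, which removes the early
prior-fitting phase of training.  Training is deterministic for a fixed
seed on a single CPU thread.

IOB2 validity is learned softly through the transition scores plus
decode-time repair; a configuration flag (`hard_transition_mask`)
switches to hard masking of invalid transitions at decode time.

Relation candidates are used exhaustively — positives are the gold
pairs, negatives every other admissible pair, with no down-sampling.
Candidates whose two entities cannot both fit in the truncation window
are dropped from training and scored 0 at prediction (logged).
Candidates with overlapping head/tail spans (possible only with a
malfunctioning upstream tagger) are skipped with a warning.

## The synthetic corpus

Annotated clinical corpora are rarely redistributable, so training,
evaluation and the acceptance checks run on generated reports with
known gold annotations.  The generator emulates the *structure* of an
annotated CT-report corpus:

* ~12 sentences per report (Poisson), with an 8.4% fraction of
  out-of-scope sentences (imaging technique / procedure /
  recommendation text) carrying no annotations — these are flagged and
  recognizable by their leading token, which is what the coverage
  metric's exclusion step consumes;
* a pseudo-clinical controlled vocabulary per entity type with a
  long-tailed (Zipf, exponent 1.1) mention distribution, so held-out
  splits contain both frequent ("major") and rare or unseen ("minor")
  mention strings;
* 0–4 modifier relations per concept, realized in template order
  (certainty/change/characteristics before the concept, size and
  location after it);
* evidence relations whose observation lies in an earlier sentence
  with probability 0.2 (the most recent previous observation), and in
  the same sentence otherwise;
* distractor structure: each report carries several observations and
  findings, so most admissible pairs are *not* related and relation
  classification cannot be solved from the type constraints alone.

What the generator does **not** emulate: real linguistic variation
(free word order, anaphora, misspellings, abbreviations), ambiguous
mention-to-type assignments, nested or discontinuous mentions, and
annotation noise.  Passing the benchmarks therefore shows that the
implementation can recover the generating annotation rules end to end —
it does not certify clinical-grade accuracy on real reports, where the
original systems of this kind reach mid-90s F1 only with substantial
pretraining.

## Evaluation

* **Entity F1** is strict: a prediction counts only when an unmatched
  gold entity has the identical type and character span; matching is
  one-to-one; aggregation is microaveraged (pool TP/FP/FN, then P/R/F1).
* **Relation F1** requires the relation type, both endpoint spans, and
  the link itself to match; modifier relations are reported per tail
  entity type.  In *gold-entities* mode predictions reference gold
  spans; in *pipeline* mode they reference predicted spans, so an
  entity boundary error costs both an FP and an FN.
* **Coverage** is (B + I) / (B + I + O) × 100 over IOB2-encoded tokens,
  with out-of-scope sentences excluded; the filtered variant also
  removes punctuation (tokens consisting solely of Unicode punctuation)
  and stop words (a plain word list, one token per line).  Zero
  eligible tokens raise an explicit undefined-metric signal rather than
  returning 0.
* **Cohen κ** = (p_o − p_e)/(1 − p_e) over two parallel binary
  labelings of the same admissible candidate set (κ needs negatives,
  hence candidates rather than annotated relations only); degenerate
  marginals (p_e = 1) raise the undefined signal.
* **Major/minor analysis** partitions test gold entities by training
  frequency of their exact surface string: ≥ 2 occurrences is major,
  ≤ 1 minor.  Predictions are assigned to a subset by the same rule
  applied to their own surface strings, so each subset pairs gold
  entities with predictions of like frequency.

## Benchmark problem sizes

The package defines two standard benchmark setups
(`radstruct.benchmark`) so tests, scripts and documentation exercise
identical conditions:

* **Parameter recovery** — 200 reports (140 train / 20 dev / 40 test,
  stratified by source tag), hidden size 128 for both models, relation
  window 48 and batch 32.  The trained tagger and classifier must reach
  ≥ 0.95 held-out micro-F1 (entity-level, and relation-level on gold
  entities).  The whole setup trains in a few minutes on one CPU.
* **Directional runs** — 60 reports (42/6/12), hidden sizes 64 (NER)
  and 32 (relation), repeated over 5 parameter-initialization seeds.
  Across seeds the mean pipeline F1 must not exceed the mean
  gold-entity relation F1 by more than 0.02 (cascade degradation), and
  mean major-mention F1 must be at least the mean minor-mention F1.

Sizes were chosen so the full suite runs in minutes on a single CPU;
the thresholds and directions above do not depend on them (larger
corpora only make the ≥ 0.95 recovery easier).

## Numerical and degenerate-input choices

* CRF internals run in float64 (the rest of the networks in float32);
  the log-partition matches brute-force enumeration to 1e-6 on
  sentences of length ≤ 5.
* Viterbi ties resolve to the lowest tag index at each backpointer.
* Empty sentence → empty tag path; empty report → no entities, no
  relations; empty corpus statistics are all-zero.
* Sentence segmentation is rule-based on terminator characters
  (default 。, newline, ASCII "."); the exact rule set used by any
  given real corpus is configuration, not an assertion.
* The tokenizer is a pluggable contract; the default regex tokenizer
  (word runs and single punctuation marks) is sufficient for the
  synthetic corpus, and a morphological analyzer can be registered for
  Japanese text without changes elsewhere.
* A token straddling a gold entity boundary is split at that boundary
  during IOB2 encoding, preserving gold spans exactly.
* BRAT relations whose arguments are listed in the reverse orientation
  are normalized to head → tail; a pair admissible in neither
  orientation is a schema error with the offending line number.

## Known limitations

* Word-level features only: no character-level encoder and no subword
  units, so unseen-token generalization rests entirely on context and
  the trained `<unk>` embedding.
* Evidence candidates are generated in the directed
  observation → clinical-finding orientation only.
* Discontinuous and overlapping gold mentions are not representable
  (IOB2/BRAT-T constraint).
* No transformer-based taggers or classifiers, no domain-adaptive
  pretraining, and no term normalization — mention strings are not
  linked to any ontology.
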