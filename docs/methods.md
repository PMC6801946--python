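# Methods

`hner` implements a two-stage approach to health-related named entity
recognition (NER) in short, noisy messages such as tweets: (1) automatic
corpus annotation by *distant supervision* against a medical concept
dictionary, and (2) a neural sequence tagger — character-CNN and word
embeddings feeding a bidirectional LSTM with a linear-chain CRF output
layer — trained on those automatic labels.  Three UMLS semantic types are
targeted throughout: T047 (disease or syndrome), T184 (sign or symptom) and
T121 (pharmacologic substance).

## Preprocessing

Raw messages are cleaned by removing whitespace-delimited tokens that start
with `http`/`https` (URLs) or `#` (hashtags), deleting every remaining
character outside `[A-Za-z0-9 ]`, lowercasing, and collapsing whitespace.
Cleaning is idempotent, and tokenization is whitespace splitting with
character offsets, so `" ".join(tokens) == clean_text` always holds.
Digits are kept by default (`keep_digits=False` removes them); dosage-like
tokens are the reason for the default.  Corpus-level filters keep documents
with at least five tokens and, after annotation, documents containing at
least one entity.

## Distant-supervision annotation

Every window of 1–5 consecutive tokens is compared against every dictionary
term with Jaccard similarity over **character 3-gram sets**:
J(a, b) = |G(a) ∩ G(b)| / |G(a) ∪ G(b)|.  Strings shorter than three
characters contribute themselves as a single gram.  A candidate is kept
when J > 0.7 (strict inequality).  The 3-gram choice reproduces the
published worked values for truncation/duplication misspellings —
diabet/diabeta 0.80, alzheime/alzheimer 0.86, obesit/obesity 0.80,
strains/strain 0.80, grimaced/grimace 0.83, illnesss/illness 0.83,
marijuan/marijuana 0.86 — which is what `scripts/acceptance.py` recomputes.
(One published value, pharmaceutica/pharmaceutical 0.71, is not consistent
with any small gram size — 3-grams give 11/12 ≈ 0.92 — and is treated as an
erratum rather than bending the definition.)

Overlapping candidates are resolved greedily by the ranking (score
descending, span length descending, leftmost first, type id ascending); a
candidate is accepted iff it shares no token with an already accepted span.
This makes the output deterministic, pairwise disjoint, and idempotent
under re-resolution.  Per-type stoplists then remove known non-medical
false positives (e.g. "water" as T121), and each surviving surface is
normalized to the canonical form of its most similar dictionary term
(ties broken lexicographically).  Spans convert losslessly to per-token
BIO tags; the reverse direction repairs dangling `I-` tags to `B-` so any
tag sequence decodes to a legal span set.

## Tagger architecture

Each token is represented by the concatenation (in fixed order) of up to
three channels; any subset can be disabled for ablations:

* **word**: a row of an embedding table (plain-text word2vec/GloVe files are
  supported; out-of-file tokens are initialized uniform in [−0.25, 0.25]).
  The table is fine-tuned by default; `finetune_embeddings=False` freezes it.
* **char** (50 dims): per-character embeddings (dimension 25, alphabet
  `[a-z0-9]` + boundary/pad/unknown) pass through three stacked width-3
  ReLU convolutions with 50 channels each and max-over-positions pooling.
  The stacking plan beyond "three layers, 50 outputs" is the package's own
  choice, following common char-CNN practice.
* **POS** (36 dims): one-hot Penn-Treebank tags from a pluggable tagger.
  The default is a small deterministic lexicon + suffix tagger; any callable
  `tokens -> tags` can be injected.

The concatenation passes through inverted dropout (rate 0.5) and a 2-layer
LSTM — bidirectional by default (per-token state is the concatenation of a
forward and a backward pass, 2×250 dims at the reference size), or
forward-only for the LSTM-CRF baseline; the two variants differ only in the
`bidirectional` flag.  A linear layer maps each context vector to K = 7
emission scores (BIO tags over three types).

A linear-chain CRF scores a tag sequence y as
`start[y_1] + Σ_t emissions[t, y_t] + Σ_t transitions[y_{t-1}, y_t] + end[y_T]`.
Explicit start/end vectors make sequence boundaries well defined; setting
them to zero recovers the matrix-only model.  The log-partition is computed
exactly by the forward recursion in log space, training minimizes
`logZ − score(gold)` (always ≥ 0), and decoding is exact Viterbi with ties
broken toward the lowest tag index.  Illegal BIO transitions are *not*
masked by default (decodes are repaired instead); `mask_illegal=True`
hard-masks them to a large negative score at decode time.

All neural computation runs on a small in-package reverse-mode autodiff
core over numpy (float64).  Its operator gradients, the batched CRF loss,
and the independent forward–backward analytic gradient are cross-checked
against central finite differences in the test suite.

## Training

Nadam (Adam with Nesterov momentum) on minibatches, with padded batches and
masking: padded steps freeze the LSTM carry state and contribute nothing to
the CRF loss.  Defaults: LSTM state 250, 2 layers, learning rate 0.001, at
most 100 epochs, dropout 0.5 on the concatenated embedding, batch size 100,
early-stopping patience 20.  After each epoch the validation set is decoded
and the support-weighted mean of per-type exact-match F1 is monitored;
training stops after `patience` epochs without improvement and restores the
best-validation parameters.  Gradients are clipped to global norm 5.

Initialization: orthogonal recurrent blocks, forget-gate bias 1, and
Glorot-uniform with **gain 2** for input/linear weights.  The gain
compensates the small dynamic range of the embedding channels (word vectors
in [−0.25, 0.25], one-hot POS rows): with it, gate pre-activations are in a
useful range from the first update, which matters because an epoch over a
small corpus is a single Adam update at the default batch size.  At desk
scale (tens to hundreds of documents) a reduced state size of 50 trains in
seconds per epoch and memorizes a 30-document corpus to exact-match F1 1.0
within the 100-epoch cap.

## Evaluation

Exact-match span evaluation: a prediction is a true positive iff a gold
span with identical token boundaries and type exists; each gold span
matches at most one prediction; a boundary-correct but type-wrong
prediction is one FP plus one FN.  Counts are pooled over documents within
each type (micro aggregation) before P = TP/(TP+FP), R = TP/(TP+FN),
F = 2PR/(P+R), with P, R, F defined as 0 when their denominators vanish.
A support-weighted aggregate over types is also reported and is the
early-stopping monitor.

## Synthetic data

The generator emulates the *structure* of an ontology-annotated tweet
corpus without any external resource: a dictionary of pronounceable
CV-syllable pseudo-terms (default 10 per type, length 4–14, every fifth
term 2–3 tokens) assigned round-robin to the three types, plus a small
stoplist; documents of 5–20 filler words (a fixed common-word vocabulary,
disjoint from all generated terms) with 1–3 planted terms.  With
probability `misspell_rate` (default 0.1) a planted term is corrupted by
one terminal-character edit — final-character deletion or duplication,
exactly the error forms the normalization examples above exhibit; gold
spans always record the uncorrupted canonical entry.  Occasionally a
stoplisted surface is planted *without* a gold span, so stoplist handling
is exercised.  Splits are a seeded shuffle followed by contiguous cuts
(default 0.6/0.2/0.2).  Everything is bit-reproducible under the spec seed.

Because fillers and terms are disjoint and corruption is a single edit, a
clean corpus is recovered perfectly by the annotator, and a fully corrupted
corpus with terms of length ≥ 7 keeps every corrupted surface above the
0.7 threshold (J ≥ (L−3)/(L−2) for deletion).  Real tweets are harder in
ways this generator deliberately does not model: ambiguous and polysemous
terms, context-dependent entities, hashtag semantics, creative spelling
beyond terminal edits, and UMLS's skewed term distribution.  Passing the
closed-loop and pipeline tests therefore demonstrates the machinery is
correct and trainable, not that real-world scores transfer.

## Desk-scale configurations used by the test suite

The capacity check trains on 30 generated documents at state size 50 with
all other defaults.  The end-to-end check uses 200 documents
(misspell rate 0.1), state size 50, patience 30, and evaluates exact-match
F1 on the held-out test split against the generator's gold spans (typical
micro F1 ≈ 0.95, asserted ≥ 0.8).  The published corpus behind the original
study (676k tweets) is not redistributable, so corpus-scale scores are out
of scope here; the package reports what it computes.

## Known limitations

* The numpy autodiff core is single-threaded and educationally simple;
  training beyond a few thousand short documents calls for a GPU framework.
* The default POS tagger is heuristic; inject a real tagger for serious use.
* Dictionary matching is O(windows × terms) with a cheap set-size pruning
  bound — fine for desk-scale dictionaries, not for all of UMLS.
* Jaccard over character 3-grams of the *joined* window surface treats
  multi-word strings as one character sequence; token-set similarity for
  multi-word terms is not implemented.
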