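# Methods

`charner` implements a character-level named-entity recognizer for
clinical-style Chinese text, consisting of a self-matching attention layer,
two bidirectional LSTM passes and a linear-chain CRF, together with the
*reduced POS tagging* preprocessing that the model's POS input feature is
designed around. This note records the model, its assumptions, the
synthetic world the package is tested on, and the numerical and design
choices that were genuinely open.

## The problem

Clinical entities in Chinese electronic medical records are the dominant
out-of-vocabulary source for word segmenters, and their lengths vary
strongly by category: anatomical parts are often 1–2 characters while
operation mentions can exceed 20. Character-level tagging avoids
segmentation errors but loses word-level semantics, and long entities make
boundary detection the hard part of the task. The model addresses both
ends: a per-character POS feature reintroduces (implicit) word boundaries,
and self-matching attention gives every character a view of the whole
sentence, which helps long-range boundary decisions.

## Reduced POS tagging

Standard word-level POS projection tags every character of a segment with
the segment's tag. Because entities are OOV, a segmenter typically cuts a
long entity such as a 7-character operation mention into pieces with
conflicting tags (noun piece + verb piece), planting a false word boundary
inside the entity. Instead of building a medical dictionary, the
preprocessing harvests a **general dictionary**: segment the *training*
split, keep every segment whose character range does not intersect any gold
entity span (partial overlaps are excluded — they are entity evidence).
At tagging time, in-dictionary segments keep their POS tag per character;
every other segment collapses uniformly to the reserved tag `s`. On unseen
text, unseen clinical entities are exactly the segments that fail the
dictionary lookup, so `s`-blocks align with entity boundaries while
ordinary context words keep informative tags.

Dictionary membership is tested on the word string alone (not word+POS);
the segmenter interface is pluggable and must be deterministic. The shipped
`ToySegmenter` is greedy longest-match over a fixed lexicon with a
single-character fallback tagged `x`; `s` is rejected as a lexicon tag to
avoid aliasing.

## Model

For an m-character sentence, character embeddings x_t ∈ R^l (l = 50) are
optionally concatenated with POS embeddings p_t ∈ R^l to give input rows
v_t. Self-matching attention scores every pair of positions,

    s_j^t = w^T tanh(W_v v_j + W_vhat v_t),
    a^t   = softmax_j(s^t),
    c_t   = Σ_j a_j^t v_j,

and a bidirectional LSTM consumes [v_t, c_t] at step t (output H, width
2k, k = 200). Attention operates on the raw input rows and c_t is computed
once and shared by both directions — the literal reading of the defining
equations. A second bidirectional LSTM re-encodes H into context features
L, and emissions are the linear map P = L W_p + b_p ∈ R^{m×n} over the
n = 2·(number of categories)+1 BIO labels.

The CRF scores a tag sequence as Σ_{i=0..m} A[y_i, y_{i+1}] + Σ_i P[i,y_i]
with virtual start/end states (the score's index range runs over both
boundaries), normalizes globally by the forward algorithm, and decodes with
Viterbi. Training minimizes the mean per-sentence negative log-likelihood.

One published equation shows the backward recurrence consuming the
*forward* previous hidden state; this is read as a typo and the standard
backward recurrence is used.

## Implementation notes

No deep-learning framework is used: the package carries a small
reverse-mode autograd engine over float64 NumPy arrays (`charner.autograd`)
and the whole network trains through it with Adam. Gradient correctness is
enforced by finite-difference checks in the test suite (elementwise with an
absolute floor of 1e-6 for entries whose central difference drowns in
float64 roundoff, plus a 1e-4 relative bound on the concatenated gradient
vector).

- **Initialization.** All weight matrices and embeddings uniform(−0.1,
  0.1); biases and initial recurrent states zero. No pretrained
  embeddings. The attention score dimension (rows of W_v) is not fixed by
  the model definition; it defaults to the LSTM hidden size.
- **Batching.** Sentences are length-sorted into batches of 32 and
  right-padded; each epoch permutes batch order with the seeded generator.
  Padded positions are pushed to −1e9 before the attention softmax, frozen
  out of the recurrent state updates, and masked in the CRF loss. Batched
  and per-sentence execution agree to 1e-5 by test.
- **Hyperparameters** (defaults): char/POS embedding 50, hidden units 200,
  Adam at 0.001, batch 32, at most 20 epochs. Training stops early when
  the mean per-sentence loss of two consecutive epochs differs by at most
  0.001 — read as a training-set criterion since no development set is
  part of the procedure. Loss is averaged over sentences within a batch so
  the learning rate is batch-size invariant.
- **CRF numerics.** Forward recursion in log space with per-step
  log-sum-exp; no scaling-factor variant. Structurally impossible
  transitions (into start, out of end) are −inf in exported potentials and
  are never read by the algorithms. The gold-path score is accumulated in
  the same transition-then-emission order as the forward recursion, so the
  single-path case (one label) gives a loss of exactly zero.
- **Decoding ties** break toward the lowest label index at every backtrack
  step, making decoding deterministic.
- **No transition masking by default**: the model must learn BIO legality,
  and illegal decoded prefixes are repaired downstream (an orphan `I_c`
  opens a span, the conlleval convention). A hard BIO mask (−1e4 on
  illegal bigrams) is available behind `TrainConfig.transition_bio_mask`.
- **Dropout** defaults to 0 (not part of the reference procedure); inverted
  dropout on the input rows is available behind `TrainConfig.dropout`.

## Evaluation

Strict matching: a predicted span is correct iff category and exact
boundaries match a gold span, each gold span matched at most once. P, R,
F1 are micro-averaged; per-category tables use the same counts restricted
by category, so the micro scores recompose exactly. Erroneous predictions
that overlap some gold span are classified against the maximally
overlapping gold span (ties: earliest-starting, then longest) into
correct-boundary/wrong-category, wrong-boundary/correct-category and
wrong-boundary/wrong-category; non-overlapping predictions are counted as
spurious, so taxonomy + TP + spurious = total predictions. Correct
entities are additionally binned by gold length into 1–5 / 6–10 / 11–15 /
>15 characters (the published bin table prints an overlapping "10–15";
the non-overlapping reading is implemented).

## Synthetic world

The reference corpus (1000 admission records, five entity categories) is
access-restricted, so the generator emulates its structure rather than its
content: five categories with mean entity lengths 2.5 / 1.5 / 2.5 / 3.4 /
7.9 characters and relative frequencies 7838 : 2066 : 3055 : 1005 : 1116
(the reference training-split statistics), entities embedded between
ordinary context words, and Chinese punctuation inserted between chunks.
Entity and context lexicon lengths are realized by stratified quantiles of
a shifted Poisson matched to the target mean, so even a 40-form lexicon
reproduces the length distribution faithfully (empirical per-category
means land within a few percent of target at ≥1000 entities, against a
15% contract). Characters come from disjoint CJK code-point blocks per
role; the text is structurally, not linguistically, Chinese-like.

Two presets define the test worlds:

- **easy**: closed per-category lexicons over per-category character
  blocks disjoint from the context block. Category identity is decidable
  from character identity, so a correctly implemented model should learn
  it nearly perfectly — this world measures that the pipeline works, not
  that the task is hard. The end-to-end criterion (strict F1 ≥ 0.90 on
  100 held-out sentences after ≤ 20 epochs at the default
  hyperparameters) runs here.
- **hard**: entity characters share the context alphabet (no
  character-identity shortcut) and categories are sampled uniformly rather
  than with the reference weights — the long category would otherwise be
  ~7% of entities, too rare for a stable 3-seed comparison at desk scale.
  Long-category surfaces are piece1+piece2 with the *pieces* (not the
  whole) in the toy segmenter's lexicon, tagged n and v, reproducing the
  mis-segmentation failure mode. The input-mode ablation
  (char+reduced_pos vs. char+pos on the long category) runs here, scaled
  to 400 train / 100 test sentences and 12 epochs with 120 hidden units
  to fit a single-CPU budget; it asserts direction with a small seed-noise
  tolerance, not an effect size.

A green easy-world test establishes that embedding, attention, recurrence,
CRF training, decoding and scoring compose correctly; it does not
establish clinical-grade accuracy, robustness to real segmenter noise, or
performance on genuinely ambiguous text. An `open_vocab_categories` option
draws a category's surfaces fresh per occurrence from a disjoint
"unknown" character block to exercise OOV handling paths.

## Known limitations

- Pure-NumPy training is single-threaded and orders of magnitude slower
  than a GPU framework; corpus sizes in the tests are chosen accordingly.
- Only the BIO scheme is supported (no BIOES/IOB1), one corpus dialect,
  and no support for the raw stand-off annotation format of the original
  dataset.
- The toy segmenter is longest-match over a closed lexicon; conclusions
  about real Chinese segmentation noise transfer only qualitatively.
- Reported scores on synthetic worlds are not comparable to published
  scores on the restricted clinical corpus.
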