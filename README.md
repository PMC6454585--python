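# charner

Character-level named-entity recognition for clinical-style Chinese text:
a self-matching attention layer over character(+POS) embeddings, two
bidirectional LSTM passes, and a linear-chain CRF, together with the
**reduced POS tagging** preprocessing that makes word-level POS features
usable on entity-heavy text.

## Who this is for

Researchers and engineers extracting clinical entities (anatomical parts,
symptom descriptions, independent symptoms, drugs, operations) from
Chinese electronic-medical-record narratives — or studying the entity
*boundary* problem that long, out-of-vocabulary clinical mentions create —
without access to a medical dictionary. The package is self-contained:
it ships a synthetic-corpus generator that reproduces the statistical
structure of such data (five categories with mean lengths 2.5 / 1.5 / 2.5 /
3.4 / 7.9 characters, entities embedded in ordinary-word context, a
segmenter that cuts long entities into differently-tagged pieces), so the
whole pipeline runs and is tested offline.

## The model

For an m-character sentence with input rows v_t (character embedding,
optionally concatenated with a POS embedding, l = 50 each):

- **Self-matching attention** — for each position t, scores against every
  position j of the same sentence

      s_j^t = wᵀ tanh(W_v v_j + W_v̂ v_t),   a^t = softmax(s^t),
      c_t = Σ_j a_j^t v_j,

  and a bidirectional LSTM (k = 200 per direction) consumes [v_t, c_t],
  giving H ∈ R^{m×2k}.
- **Context layer** — a second BiLSTM: L = BiLSTM(H) ∈ R^{m×2k}.
- **CRF** — emissions P = L W_p + b_p ∈ R^{m×n}; sequence score
  s(V, y) = Σ_{i=0..m} A[y_i, y_{i+1}] + Σ_{i=1..m} P[i, y_i] with virtual
  start/end states; p(y|V) = exp s(V,y) / Σ_ỹ exp s(V,ỹ); training
  minimizes −log p(y|V) (forward algorithm, log-space); decoding is exact
  Viterbi.

**Reduced POS tagging**: segment the training split, collect every segment
that does not intersect a gold entity span into a *general dictionary*;
at tagging time keep POS tags only for in-dictionary segments and collapse
all other segments — i.e. the likely entities — to the reserved tag `s`,
uniformly over their characters. Unseen entities then surface as clean
`s`-blocks instead of spuriously segmented tag sequences.

Everything trains through a small in-repo reverse-mode autograd engine on
NumPy (no deep-learning framework required); gradients are validated
against finite differences in the test suite.

## Worked example

```python
import charner as ch
from charner.model import TrainConfig
from charner.pos_preprocess import build_general_dictionary, apply_pos_tagging

# a 600-sentence synthetic world; 500 train / 100 held out
bundle = ch.generate_corpus(ch.easy_corpus_spec(seed=7, n_sentences=600))
train_s, test_s = bundle.sentences[:500], bundle.sentences[500:]

seg = bundle.segmenter
gdict = build_general_dictionary(train_s, seg)
train_t = apply_pos_tagging(train_s, seg, mode="reduced", dictionary=gdict)
test_t = apply_pos_tagging(test_s, seg, mode="reduced", dictionary=gdict)

result = ch.train(TrainConfig(input_mode="char+reduced_pos", seed=1), train_t)
report = ch.evaluate(bundle.spans[500:], ch.predict_spans(result.model, test_t))
print(f"P={report.precision:.4f} R={report.recall:.4f} F1={report.f1:.4f}")
```

This run prints (about a minute of single-CPU training; fully
deterministic for the fixed seeds):

```
P=0.9558 R=0.9558 F1=0.9558
```

i.e. strict entity-level scores — a predicted entity counts only when its
category *and* exact boundaries match the gold span. `report` also carries
per-category scores, the boundary/category error taxonomy and a histogram
of correct entities by gold length (1–5 / 6–10 / 11–15 / >15 characters).

On the harder generator preset (`hard_corpus_spec`, shared alphabets, long
entities mis-segmented into noun+verb pieces), the same protocol shows the
point of the preprocessing: mean Operation-category F1 over 3 seeds is
0.67 with `char+reduced_pos` input vs 0.20 with plain projected POS
(`char+pos`).

A CLI mirrors the pipeline: `charner synth | build-dict | reduce-pos |
train | predict | evaluate` (see `charner --help`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic world from the seed, runs the full pipeline
(dictionary construction, reduced POS tagging, training at the default
hyperparameters, strict held-out evaluation) and prints the scores, the
error taxonomy and the length histogram, then writes the JSON result
file. Runtime is a few minutes on one CPU.
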