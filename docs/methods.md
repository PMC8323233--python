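# Methods

## Task and model

The package recognizes clinical named entities in Chinese chest-CT findings
at the character level. Fourteen entity categories cover lung-cancer
screening and staging information (mass descriptions and their attributes —
location, size, shape, density, enhancement — plus lymph-node mentions,
invasion of vessels, pleura, bronchi and vertebral bodies, pulmonary
atelectasis/obstructive pneumonitis, effusion, and negation cues). A
sentence of characters `c_1..c_n` is tagged with BIO labels (`B-T`/`I-T`/`O`
over the 14 types, 29 labels), and spans are the maximal `B-T I-T*` runs.

The tagger ("btn" variant) is

    embeddings → BiLSTM → Transformer encoder layer → linear head → linear-chain CRF

* **Embedding layer.** A pluggable provider mapping characters to
  D-dimensional vectors. The reference provider is a static lookup table
  (the FastText-style baseline family); a contextual provider (e.g. a
  masked-LM encoder) plugs in through an adapter with per-sentence caching
  and is frozen by default. The lookup table is *trainable* by default in
  supervised training — the standard regime for a lookup embedding layer —
  and always frozen during pre-training.
* **BiLSTM.** Standard gate equations (input/forget/cell/output), forward
  and backward states concatenated (width `2H`). It supplies local,
  order-sensitive context; padded positions propagate zeros.
* **Transformer layer.** Scaled dot-product self-attention
  `softmax(QKᵀ/√d_k)V` with `h` heads, output projection, residual
  connection and layer norm, then a position-wise feed-forward block with
  its own residual + layer norm. Post-norm ordering is used — the
  convention of the original Transformer encoder; pre-norm is the
  alternative and this choice is a genuinely open design point here.
  The BiLSTM output is linearly projected to the Transformer width.
  Positional encodings are **off** for variants containing the BiLSTM
  (recurrence already encodes order) and sinusoidal encodings are **on**
  for the `transformer_only` ablation, which is otherwise
  permutation-equivariant.
* **CRF.** Transition table over the 29 labels plus START/STOP states.
  Training maximizes the exact sequence log-likelihood
  `score(y|x) − log Z(x)` with the partition function computed by the
  forward algorithm; decoding is Viterbi; per-position posteriors come from
  forward–backward. All path algebra is carried out in log space with
  max-subtraction. Transition constraints are *learned*; an optional flag
  hard-masks BIO-invalid transitions (default off). Viterbi ties break
  toward the lower label index.

Two ablations are first-class: `bilstm_only` (no Transformer) and
`transformer_only` (no BiLSTM, positional encodings on).

All tensor computation runs on a small reverse-mode automatic
differentiation engine over NumPy arrays (`btner.autograd`), written for
this package and verified against numerical differentiation in the test
suite. Training uses Adam with global gradient-norm clipping at 5 (a
standard stabilizer for recurrent stacks, stated here as this package's
addition).

## Unsupervised pre-training

Before supervised training, the trunk (BiLSTM, Transformer layer,
projection) plus a tanh regression head can be pre-trained on unlabeled
reports. Character-level TF-IDF is computed with one document per report:

    TFIDF(w, d) = TF(w, d) · log(N / DF(w))        (natural log)

then min–max normalized to [0, 1] (one global min–max over all stored
(w, d) pairs by default; a per-document scope is available behind a flag).
The log base is immaterial: any fixed base rescales all values by a
constant that the min–max normalization removes. The regression target for
character `i` of document `d` is

    y*_i = TFIDF_normalized(c_i, d) · E(c_i)

where `E` is the provider's embedding (the static table row for lookup
providers). The objective is the mean over tokens of the squared Euclidean
distance `‖ŷ_i − y*_i‖²`, averaged over sentences in a batch; `ŷ` comes
from the tanh head, so its components lie in (−1, 1) and
`‖y*_i‖ ≤ ‖E(c_i)‖` always. Only the trunk and the regression head are
updated; the embedding provider, the label head and the CRF are frozen
(enforced by checksums). The pre-training corpus must exclude test-split
documents; a guard raises on contamination. The supervised stage then
warm-starts from the trunk weights only (the regression head is discarded
and the label head and CRF start fresh).

Pre-training batch size defaults to 32 (the supervised batch size of 8
belongs to the tagging protocol; the dense regression objective tolerates
larger batches and runs ~4× faster with them).

## Supervised protocol

* **Split**: document-level random 70/10/20 partition; sizes are
  `floor(r·M)` with the remainder assigned to the training split
  (M = 359 → 253/35/71); deterministic per seed.
* **Optimization**: Adam, lr 1e-4, batch size 8, loss averaged per
  sentence (not per character), length-bucketed batches.
* **Early stopping**: validation exact-match macro-F1, patience 5
  (the monitored quantity is a package choice; only the use of a
  validation-based stop is part of the protocol).
* **Grid search**: exhaustive product over declared candidate sets
  (lr ∈ {1e-4, 5e-4, 1e-3, 5e-3}, dropout ∈ {0,…,0.5}, batch ∈ {8,16},
  LSTM layers ∈ {1,2}, hidden ∈ {64,128}, Transformer layers ∈ {1,2,3,5},
  heads ∈ {1,2,3,4,6,8,12}), ranked by validation exact-match macro-F1,
  ties to the smaller model then first-seen order. The default operating
  point (hidden 128, 1 LSTM layer, 1 Transformer layer, 1 head, dropout
  0.13, batch 8, lr 1e-4) validates against this space, with one caveat:
  the selected dropout 0.13 is not a grid point of the declared dropout
  set, so the validation rule checks dropout by hull membership
  (min ≤ value ≤ max) and every other default by set membership.
* **Multi-run reporting**: metrics over ≥2 seeds are reported as
  mean ± sample standard deviation (ddof = 1); e.g. {80, 90} → 85.00 ± 7.07.

## Evaluation

Entity-level precision/recall/F1 under two schemes. **Exact** match
requires identical (type, start, end); **inexact** requires the same type
and character-interval overlap (cross-type overlap credit exists behind a
flag, default off). Matching is one-to-one within each sentence: greedy
left-to-right by gold start, each gold span taking the first overlapping
unused prediction. For interval-overlap graphs over two internally
non-overlapping span sets this greedy assignment attains maximum
cardinality; the tests enforce agreement with a brute-force
maximum-matching oracle. TP + FN = |gold| and TP + FP = |predictions|
per type; inexact metrics dominate exact metrics everywhere, and the
package asserts this on every evaluation. Macro aggregates average over
gold-present types only; micro pools global counts; 0/0 ratios report 0.
Annotator agreement is Cohen's kappa over per-character BIO labels
(`B-T`/`I-T`/`O` all distinct).

## Synthetic corpus generator

The generator emulates the *statistical* structure of an annotated
chest-CT findings corpus, not its prose. Sentences follow a clause
grammar (negation, then location → mass → attributes, lymph, invasion,
effusion clauses); each entity's surface form is sampled from a per-type
sublexicon of CJK characters at a length drawn from a shifted
negative-binomial; background characters fill the gaps. Defaults mirror a
real corpus's per-type relative frequencies (location and negation
mentions dominate) and mean span lengths (vessel ≈ 10.8 and vertebral-body
≈ 13.8 characters; most attribute types 4–5). With the default disjoint
sublexicons the task is separable — every entity character identifies its
type — so near-perfect F1 is learnable; an `ambiguity` knob shares
surface forms between confusable pairs (pleura/bronchus, mass/lymph) to
make typing context-dependent. A `negation_rate` knob inserts *extra*
negation tokens before negatable clauses (default 0: negation mentions
already arise from the type frequencies).

What the generator does **not** emulate: real lexical statistics (its
character inventory is small and near-uniform, where real text is
Zipfian), discourse structure across sentences, co-occurrence constraints
between attribute values, or annotation noise. Passing tests on this
corpus therefore demonstrate that the machinery — coding, inference,
optimization, evaluation — is correct and that the architecture can learn
a separable character-level tagging task at the stated budgets; they say
nothing about clinical accuracy on real reports.

A fixed fixture (seed 13, 400 documents) is generated deterministically at
call time (`btner.fixtures.fixture_corpus`) and anchors the regression
tests.

## Experiment problem sizes

The protocol experiments (`btner.experiments`) run at desk scale on one
CPU: embedding 32, hidden 64, one Transformer layer with one head, dropout
0.13, batch 8, lr 1e-4. The pre-training contract run uses the full
400-document fixture for 5 epochs; the warm-vs-cold comparison uses a
150-document fixture prefix (pre-train 5 epochs, then one supervised epoch
per arm per seed); the separable benchmark trains on ~500 sentences (whole
documents from the 70% split of a 130-document corpus, seed 13) for at
most 30 epochs and evaluates on the held-out 20%.

## A negative result, stated plainly

Warm-starting supervised training from the pre-trained trunk does **not**
lower first-epoch training loss on the synthetic fixture — the cold start
is consistently better there (the acceptance suite computes this
comparison and currently reports 0 of 3 seeds in favour of warm starting).
Diagnosis: on this corpus the TF-IDF regression drives the trunk into a
low-gain region (warm-start gradient norms are several times smaller than
cold-start ones), which slows early supervised adaptation; the effect is
unchanged under either normalization scope, frozen or trainable
embeddings, with or without gradient clipping, and for both partially and
fully converged pre-training. The convergence benefit attributed to this
pre-training scheme on real clinical text with contextual embeddings
depends on properties (Zipfian character statistics, meaningful embedding
geometry) that the synthetic generator deliberately does not reproduce.
The stage itself is implemented and verified against hand-computed
fixtures; its transfer benefit on real data is untested here.

## Numerical and degenerate-case choices

* Min–max normalization with max = min maps every value to 0.
* Precision/recall with zero denominators report 0.
* Macro-F1 over an empty gold set is 0.
* `bio_decode` repairs dangling `I-T` (treated as `B-T`) when decoding
  model predictions; gold data decodes strictly and fails loudly.
* Empty sequences are rejected by all CRF routines.
* Parameters initialize Glorot-uniform from a seeded generator; the CRF
  transition table initializes at zero.
* Checkpoints serialize parameters to JSON; Python float round-tripping
  makes reloads bit-exact.

## Known limitations

* No GPU path; the autodiff engine is adequate for desk-scale corpora
  (seconds per epoch on hundreds of sentences) but not for large corpora.
* No nested or discontinuous entities; spans within a sentence must not
  overlap.
* No beam search; decoding is exact Viterbi.
* The contextual-provider contract ships with a toy self-attention
  provider for tests; integrating a real pretrained encoder is documented
  but not bundled.
* Five-run averaging supports both fixed-split/different-init and
  re-split-per-run designs; re-splitting is the default.
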