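# Methods

## Encodings

Four nucleotide-to-number mappings are implemented. The three static
schemes substitute a fixed value per base: integer (A=1, C=3, G=2, T=4),
atomic number (A=70, C=58, G=78, T=66) and EIIP electron–ion interaction
potentials (A=0.1260, C=0.1340, G=0.0806, T=0.1335). The dynamic BFDNA
scheme assigns position *i* the relative frequency of its own base within
the whole sequence, count/length — the term-frequency statistic of text
processing restricted to a 4-symbol alphabet. Its values always lie in
[0, 1] and the four distinct per-base values sum to 1 for pure-ACGT
sequences.

Input handling: residues are upper-cased before validation (FASTA files
mix soft-masked and upper case). Strict mode admits only A/C/G/T and
reports the position and symbol of the first violation. Lenient mode
additionally admits IUPAC ambiguity codes, encoding them as the pad value
(0) under every scheme; for BFDNA they are excluded from the base counts
but kept in the length denominator, keeping "total sequence length"
literal. Ambiguity handling is a convention, not a claim about biology —
datasets with many Ns should be cleaned upstream.

### Preprocessing

Min–max normalization maps values through (v − min)/(max − min) using the
scheme's **theoretical alphabet extremes** (integer 1–4, atomic 58–78,
EIIP 0.0806–0.1340, BFDNA 0–1) rather than per-dataset empirical extremes.
This makes the transform deterministic and leak-free across
train/validation/test splits; it was a genuinely open choice and the
deterministic option was preferred. Fixed-length model input is produced
by truncating to the 5′ prefix or padding with 0 at the 3′ end; the
default window is 1024 positions (enhancer elements run ≈1–3 kb), 200 in
scaled-down mode. BFDNA frequencies are always computed on the full,
untruncated sequence, because the statistic is defined on the sequence,
not on the model's input window.

## Metric panel

All scalar metrics are computed from one-vs-rest confusion counts
(TP, FP, TN, FN): accuracy (TP+TN)/total, precision, recall, specificity,
F1, CSI = precision + recall − 1 ∈ [−1, 1], G-mean =
√(recall × specificity), Matthews correlation, and binary Cohen's kappa
2(TP·TN − FP·FN)/[(TP+FP)(FP+TN) + (TP+FN)(FN+TN)]. Zero denominators in
precision/recall/specificity return 0 with a warning by default
(configurable to raise), keeping batch evaluation total; MCC returns 0
when a marginal is empty (the standard convention); kappa raises on a zero
denominator.

Multi-class evaluations macro-average the one-vs-rest scalar metrics with
equal class weight, treating classes symmetrically. Accuracy is the
exception: it is reported as the overall fraction correct (equal to the
micro average), because one-vs-rest accuracy inflates mechanically with
class count and the overall rate is what a single headline accuracy figure
conventionally means.

ROC curves and AUC use trapezoidal integration via scikit-learn. Micro
averaging pools every one-vs-rest (label, score) pair before building one
curve; macro averaging builds per-class curves, interpolates TPR on a
common FPR grid and averages AUCs with equal weight, skipping (with a
warning) classes absent from the truth. Class order is alphabetical
throughout; in binary problems the alphabetically first class is the
positive class and its score column drives the ROC.

Qualitative bins: AUC < 0.50 no distinction, 0.50–0.69 poor, 0.70–0.79
acceptable, 0.80–0.89 great, ≥ 0.90 outstanding (half-open bins, upper
edge exclusive except 1.0). Kappa: < 0.10 no agreement, 0.10–0.20 slight,
0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 substantial, 0.81–0.99
almost perfect, 1.0 perfect. The conventional tables leave the intervals
(0, 0.10) and (0.20, 0.21) unassigned; continuous half-open bins close
those gaps, with sub-0.10 values reading as no agreement.

## Classifier stacks

Both scenarios share the layer grammar: [BiLSTM → dropout]* → batch
normalization → flatten → dense stack → output. Every BiLSTM emits
per-position outputs (forward and backward passes concatenated), which
both lets recurrent layers stack and gives the flatten layer the full
sequence, as the batch-norm-then-flatten ordering requires.

* Scenario 1 (binary): BiLSTM 256/128/64, dropout 0.15/0.20/0.20, dense
  512/256/128, single sigmoid output; binary cross-entropy, RMSProp.
* Scenario 2 (3-class): BiLSTM 128/64, dropout 0.15/0.20, dense 256/128,
  softmax output; categorical cross-entropy, Adam.

Recurrent activations are SELU (applied to the candidate and cell-output
nonlinearities; gates stay sigmoidal). Hidden dense layers use ReLU, a
conventional default where no activation is dictated. The output layer is
computed as logits fused with the cross-entropy loss for numerical
stability; sigmoid/softmax are applied at prediction time, so the decision
rule (0.5 threshold / argmax) is unchanged.

### Numerical choices

The whole engine is numpy. Weights are Glorot-uniform (input kernels) and
orthogonal (recurrent kernels) with forget-gate bias 1. Because SELU is
unbounded above, the LSTM cell state can drift without limit over
thousand-step sequences and saturate the gates; the cell state is
therefore clipped to ±3 after each update (a standard LSTM stabilization),
with the clip's gradient mask applied in backpropagation. Gradients are
globally norm-clipped at 5. RMSProp uses ρ = 0.9, Adam β = (0.9, 0.999);
both default to learning rate 0.001 (the conventional default — the
training regime specifies no rate) and batch size 32. Backpropagation
through time is exact (verified against central finite differences to
~1e-8 relative error in the test suite). Training aborts with the epoch
and batch index if the loss becomes non-finite.

Training runs a fixed epoch budget with no early stopping (the reference
regime is a fixed 500 epochs; scaled-down runs use ≤ 50). Runs are
reproducible on one device: a single integer seed drives weight
initialization, dropout masks, batch shuffling and the data split.

### Splits

The train/validation/test split defaults to 0.70/0.15/0.15 — the stated
75%/15%/15% split sums to 105% and is unsatisfiable, so the training share
absorbs the overrun; fractions are configurable. Splitting is stratified
by label, shuffles within class under the run seed, rounds class
allocations to nearest, and errors if any class has fewer members than the
three partitions. Partitions are checked disjoint by sequence id before
training.

## Synthetic data

The generator emulates a labeled enhancer corpus: 2 or 3 classes
(human_enhancer / mouse_enhancer / no_enhancer), per-class nucleotide
composition vectors, lengths uniform on 1000–3000 bases by default (real
curated elements run ≈1–3 kb), drawn i.i.d. per position. Composition is
the only class signal; the in-scope encodings are composition- or
identity-driven, so an i.i.d. model is sufficient to exercise every
pipeline stage. It deliberately does **not** simulate enhancer motifs,
dinucleotide structure, conservation or chromatin context — passing tests
demonstrate that the pipeline recovers a planted compositional signal, not
that it would attain any particular accuracy on real enhancers.

The `strong` preset pairs (0.40, 0.40, 0.10, 0.10) against the uniform
(0.25, 0.25, 0.25, 0.25), adding (0.10, 0.55, 0.25, 0.10) as the third
class: every pair differs by ≥ 0.15 in at least two bases. One subtlety
drove this choice: the expected per-position BFDNA value equals the sum of
squared base frequencies, which is invariant under permuting a composition
vector. Two classes whose compositions are permutations of each other are
therefore *invisible* to BFDNA at the value level even though they are
trivially separable to a base-identity encoding. The preset compositions
are deliberately non-permutations with distinct squared-frequency sums
(0.34 / 0.25 / 0.385), so the dynamic scheme sees the signal. The
`moderate` preset halves the differences; `none` uses identical
compositions, giving the chance-level null used to guard against leakage.

## Desk-scale test sizes

The test suite exercises the full architecture only in scaled-down form:
widths ÷ 8, input window 200, 600 sequences, ≤ 30 epochs for the
separability check, and smaller still (units 8/4, windows ≤ 100,
15 epochs, 5 matched seeds) for the encoding-comparison median. These
sizes are the package's chosen desk-scale study conditions; full-size
500-epoch runs on the complete architecture are supported through the same
API and CLI but are not exercised by the tests.

## Known limitations

* The i.i.d. composition model cannot probe order-sensitive behaviour; a
  motif-planting generator would be needed to study what the BiLSTM adds
  over a bag-of-bases classifier.
* BFDNA collapses base identity into frequency: compositionally
  equivalent-but-permuted classes are indistinguishable (see above), a
  structural property of the encoding, not a bug.
* The numpy engine targets clarity and desk scale, not throughput; there
  is no GPU path.
* The VISTA header parser is best-effort: export conventions vary and the
  exact snapshot/filtering of any given study is not recoverable, so label
  mapping from real exports should be reviewed before use.
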