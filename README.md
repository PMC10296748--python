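# bfdna

Numeric DNA encodings for deep-learning sequence classification, built
around **BFDNA** — a dynamic, term-frequency-style encoding in which each
position of a sequence takes the within-sequence relative frequency of its
own base — together with the three classic static comparators (integer,
atomic number, EIIP), two bidirectional-LSTM enhancer classifiers, and a
nine-metric evaluation panel. It is aimed at regulatory-genomics
practitioners who want to compare nucleotide-to-number mappings as inputs
to recurrent classifiers of enhancer sequences (e.g. VISTA Enhancer
Browser exports), and at anyone who needs the encodings or the metric panel
on their own.

## The encodings

For a sequence $S = s_1 s_2 \dots s_L$ over $\{A, C, G, T\}$:

| scheme  | rule | nature |
|---------|------|--------|
| integer | $A{\to}1,\ C{\to}3,\ G{\to}2,\ T{\to}4$ | static |
| atomic  | $A{\to}70,\ C{\to}58,\ G{\to}78,\ T{\to}66$ | static |
| EIIP    | $A{\to}0.1260,\ C{\to}0.1340,\ G{\to}0.0806,\ T{\to}0.1335$ | static |
| BFDNA   | $s_i \to \mathrm{count}(s_i \text{ in } S)\,/\,L$ | dynamic |

BFDNA is the term-frequency idea from text processing on the 4-letter DNA
alphabet: the value of a base depends on the whole sequence, so the same
base encodes differently in different sequences. Encoding `ACACCCAGGT`
gives `[0.3 0.4 0.3 0.4 0.4 0.4 0.3 0.2 0.2 0.1]` (three A's, four C's,
two G's, one T over length ten).

## The classifiers

Two stacked-BiLSTM models with SELU recurrent activations:

* **scenario 1** (binary: human vs mouse enhancer): BiLSTM 256/128/64 with
  dropout 0.15/0.20/0.20 → batch norm → flatten → dense 512/256/128 →
  sigmoid; binary cross-entropy, RMSProp.
* **scenario 2** (3-class: human / mouse / no enhancer): BiLSTM 128/64 with
  dropout 0.15/0.20 → batch norm → flatten → dense 256/128 → softmax;
  categorical cross-entropy, Adam.

The recurrent stack, backpropagation-through-time and the optimizers are
implemented in numpy inside the package (`bfdna.nn`) and verified against
finite-difference gradients in the test suite. A scaled-down mode (widths
÷ 8, short input window) runs the identical architecture at desk scale.

Evaluation reports accuracy, precision, recall, specificity, F1,
CSI (precision + recall − 1), G-mean (√(recall·specificity)), Matthews
correlation, Cohen's kappa, and micro/macro ROC-AUC, with the conventional
qualitative bins for AUC and kappa.

## Worked example

```python
from bfdna import (NucleotideSequence, encode_bfdna, generate_dataset,
                   preset_separable, ModelSpec, TrainConfig, run_scenario)

print(encode_bfdna(NucleotideSequence("ex", "ACACCCAGGT")).values)
# [0.3 0.4 0.3 0.4 0.4 0.4 0.3 0.2 0.2 0.1]

# synthetic 2-class dataset with strongly separated base compositions
ds = generate_dataset(preset_separable("strong", n_classes=2, n_per_class=300, seed=11))
spec = ModelSpec.scaled_down(1, input_length=200)
result, history = run_scenario(ds, "bfdna", spec, TrainConfig(scenario=1, epochs=30, seed=11))
print(result.report.accuracy, result.report.kappa, result.report.auc_macro)
# 1.0 1.0 1.0
print(result.report.interpretations()["kappa"])
# Perfect agreement
```

The run splits 600 sequences 70/15/15 into train/validation/test, encodes
them with BFDNA, trains the scaled-down scenario-1 BiLSTM for 30 epochs and
scores the held-out 90 sequences: with compositions this far apart the
planted signal is recovered perfectly.

The same workflow is available from the shell:

```sh
bfdna simulate --preset strong --seed 7 --out runs/
bfdna encode runs/synthetic.fasta --scheme bfdna --label-dialect header-pipe --out runs/
bfdna train-eval --preset strong --scheme bfdna --scenario 1 --scaled-down --out runs/
bfdna metrics predictions.csv        # recompute the panel from saved predictions
```

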