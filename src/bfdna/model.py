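"""The two BiLSTM enhancer-classifier stacks and their training workflow.

Scenario 1 (binary, human vs mouse enhancer) stacks three bidirectional
LSTM layers of 256/128/64 units with SELU activations and dropout
0.15/0.20/0.20, then batch normalization, flatten, dense layers 512/256/128
and a single sigmoid output, trained with binary cross-entropy under
RMSProp. Scenario 2 (3-class: human enhancer / mouse enhancer / no
enhancer) stacks 128/64-unit BiLSTMs with dropout 0.15/0.20, batch
normalization, flatten, dense 256/128 and a softmax output, trained with
categorical cross-entropy under Adam. Both default to 500 training epochs
and a 70/15/15 train/validation/test split.

A scaled-down mode (units divided by 8, short input window, few epochs)
exercises the identical architecture at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .dataset import LabeledDataset
from .encodings import encode_matrix
from .metrics import MetricReport, metric_report

SCENARIO_DEFAULTS = {
    1: dict(
        recurrent_units=[256, 128, 64],
        dropout_rates=[0.15, 0.20, 0.20],
        dense_units=[512, 256, 128],
        output_activation_name="sigmoid",
        n_classes=2,
    ),
    2: dict(
        recurrent_units=[128, 64],
        dropout_rates=[0.15, 0.20],
        dense_units=[256, 128],
        output_activation_name="softmax",
        n_classes=3,
    ),
}

SCENARIO_LOSS = {1: "binary_crossentropy", 2: "categorical_crossentropy"}
SCENARIO_OPTIMIZER = {1: "rmsprop", 2: "adam"}


@dataclass
class ModelSpec:
    """Declarative description of one BiLSTM classifier stack."""

    scenario: int
    recurrent_units: list[int]
    dropout_rates: list[float]
    dense_units: list[int]
    recurrent_activation_name: str = "selu"
    output_activation_name: str = "sigmoid"
    input_length: int = 1024
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2):
            raise ValueError(f"scenario must be 1 or 2, got {self.scenario}")
        if len(self.recurrent_units) != len(self.dropout_rates):
            raise ValueError(
                f"recurrent_units ({len(self.recurrent_units)}) and dropout_rates "
                f"({len(self.dropout_rates)}) must have the same length"
            )
        if self.input_length < 1:
            raise ValueError("input_length must be >= 1")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")

    @classmethod
    def for_scenario(cls, scenario: int, input_length: int = 1024, scale: int = 1) -> "ModelSpec":
        """The canonical stack for a scenario, optionally width-divided by ``scale``."""
        d = SCENARIO_DEFAULTS[scenario]
        return cls(
            scenario=scenario,
            recurrent_units=[max(1, u // scale) for u in d["recurrent_units"]],
            dropout_rates=list(d["dropout_rates"]),
            dense_units=[max(1, u // scale) for u in d["dense_units"]],
            output_activation_name=d["output_activation_name"],
            input_length=input_length,
            n_classes=d["n_classes"],
        )

    @classmethod
    def scaled_down(cls, scenario: int, input_length: int = 200) -> "ModelSpec":
        """Desk-scale variant: layer widths divided by 8, short input window."""
        return cls.for_scenario(scenario, input_length=input_length, scale=8)


@dataclass
class TrainConfig:
    """Training regime for one scenario run."""

    scenario: int
    epochs: int = 500
    batch_size: int = 32
    learning_rate: float = 0.001
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    loss_name: str = ""
    optimizer_name: str = ""

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"split fractions must sum to 1, got {self.split_fractions} "
                f"(sum {sum(self.split_fractions)})"
            )
        if not self.loss_name:
            self.loss_name = SCENARIO_LOSS[self.scenario]
        if not self.optimizer_name:
            self.optimizer_name = SCENARIO_OPTIMIZER[self.scenario]


@dataclass
class EvaluationResult:
    """Test-set scores plus the confusion table for one encoding/scenario run."""

    report: MetricReport
    confusion_table: np.ndarray  # (k, k), rows = true class, cols = predicted
    classes: list[str]
    scenario: int
    scheme: str

    def __post_init__(self) -> None:
        self.confusion_table = np.asarray(self.confusion_table)


def build_model(spec: ModelSpec) -> nn.Sequential:
    """Materialize a spec as an (unbuilt) layer stack.

    Layer order: [BiLSTM -> dropout]* -> batch norm -> flatten ->
    dense stack (ReLU) -> output. Every BiLSTM emits per-position outputs so
    the recurrent layers stack and the flatten sees the full sequence. The
    output layer is linear here; sigmoid/softmax live in the fused loss and
    are applied at prediction time.
    """
    layers: list[nn.Layer] = []
    for units, rate in zip(spec.recurrent_units, spec.dropout_rates):
        layers.append(nn.BiLSTM(units, activation=spec.recurrent_activation_name))
        layers.append(nn.Dropout(rate))
    layers.append(nn.BatchNorm())
    layers.append(nn.Flatten())
    for units in spec.dense_units:
        layers.append(nn.Dense(units, activation="relu"))
    out_units = 1 if spec.n_classes == 2 else spec.n_classes
    layers.append(nn.Dense(out_units, activation="linear"))
    return nn.Sequential(layers, loss=SCENARIO_LOSS[spec.scenario])


def split_dataset(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    stratified: bool = True,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive train/validation/test partition.

    Stratified mode shuffles and allocates within each class so split
    proportions hold per class; sizes follow round-to-nearest with the test
    partition absorbing the remainder.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(seed)

    def allocate(indices: np.ndarray) -> tuple[list[int], list[int], list[int]]:
        n = len(indices)
        n_train = round(fractions[0] * n)
        n_val = round(fractions[1] * n)
        n_train = min(n_train, n)
        n_val = min(n_val, n - n_train)
        return (
            list(indices[:n_train]),
            list(indices[n_train : n_train + n_val]),
            list(indices[n_train + n_val :]),
        )

    if stratified:
        parts: tuple[list[int], list[int], list[int]] = ([], [], [])
        labels = np.asarray([s.label for s in dataset])
        for cls in sorted(set(labels)):
            cls_idx = np.flatnonzero(labels == cls)
            if len(cls_idx) < 3:
                raise ValueError(
                    f"class {cls!r} has {len(cls_idx)} members, fewer than the 3 partitions"
                )
            rng.shuffle(cls_idx)
            for part, got in zip(parts, allocate(cls_idx)):
                part.extend(got)
    else:
        order = rng.permutation(len(dataset))
        parts = allocate(order)

    return tuple(dataset.subset(sorted(p)) for p in parts)  # type: ignore[return-value]


def prepare_inputs(
    dataset: LabeledDataset,
    scheme: str,
    spec: ModelSpec,
    strict: bool = True,
    classes: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Encode sequences and labels into model-ready arrays.

    Returns ``(X, y, classes)`` where X is (n, input_length, 1), classes are
    in alphabetical order, and y is a 0/1 vector (binary; the alphabetically
    first class is positive and coded 1) or a one-hot matrix (multi-class).
    Pass ``classes`` explicitly when encoding a subset, so the coding matches
    the full dataset's label universe.
    """
    if classes is None:
        classes = dataset.label_universe()
    x = encode_matrix(list(dataset), scheme, spec.input_length, strict=strict)[:, :, None]
    idx = {c: i for i, c in enumerate(classes)}
    codes = np.asarray([idx[s.label] for s in dataset])
    if spec.n_classes == 2:
        if len(classes) != 2:
            raise ValueError(f"scenario 1 needs exactly 2 classes, found {classes}")
        y = (codes == 0).astype(float)  # positive class = alphabetically first
    else:
        y = np.zeros((len(dataset), spec.n_classes))
        y[np.arange(len(dataset)), codes] = 1.0
    return x, y, classes


def train(
    model: nn.Sequential,
    train_data: tuple[np.ndarray, np.ndarray],
    validation_data: tuple[np.ndarray, np.ndarray] | None,
    config: TrainConfig,
) -> nn.History:
    """Build (if needed) and fit the model under a training config."""
    x, y = train_data
    if not model.built:
        model.build(x.shape[1:], seed=config.seed)
    optimizer = nn.OPTIMIZERS[config.optimizer_name](learning_rate=config.learning_rate)
    return model.fit(
        x,
        y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        optimizer=optimizer,
        validation_data=validation_data,
        seed=config.seed,
    )


def evaluate(
    model: nn.Sequential,
    test_data: tuple[np.ndarray, np.ndarray],
    classes: list[str],
    scenario: int,
    scheme: str,
) -> EvaluationResult:
    """Score a trained model on held-out data, Tables-style row + confusion."""
    x, y = test_data
    if len(x) == 0:
        raise ValueError("test set is empty")
    proba = model.predict_proba(x)
    if proba.ndim == 1:
        true = [classes[0] if t == 1 else classes[1] for t in y]
        pred = [classes[0] if p >= 0.5 else classes[1] for p in proba]
        scores = proba
    else:
        true = [classes[i] for i in y.argmax(axis=1)]
        pred = [classes[i] for i in proba.argmax(axis=1)]
        scores = proba
    report = metric_report(true, pred, scores=scores, positive_class=classes[0])
    k = len(classes)
    table = np.zeros((k, k), dtype=int)
    cidx = {c: i for i, c in enumerate(classes)}
    for t, p in zip(true, pred):
        table[cidx[t], cidx[p]] += 1
    return EvaluationResult(
        report=report, confusion_table=table, classes=classes, scenario=scenario, scheme=scheme
    )


def run_scenario(
    dataset: LabeledDataset,
    scheme: str,
    spec: ModelSpec,
    config: TrainConfig,
    strict: bool = True,
) -> tuple[EvaluationResult, nn.History]:
    """End-to-end: split, encode, train, evaluate. Returns result + history."""
    train_set, val_set, test_set = split_dataset(
        dataset, fractions=config.split_fractions, seed=config.seed
    )
    if set(train_set.ids) & set(val_set.ids) or set(train_set.ids) & set(test_set.ids) \
            or set(val_set.ids) & set(test_set.ids):
        raise RuntimeError("train/validation/test partitions overlap")
    classes = dataset.label_universe()
    xtr, ytr, _ = prepare_inputs(train_set, scheme, spec, strict=strict, classes=classes)
    xva, yva, _ = prepare_inputs(val_set, scheme, spec, strict=strict, classes=classes)
    xte, yte, _ = prepare_inputs(test_set, scheme, spec, strict=strict, classes=classes)
    model = build_model(spec)
    history = train(model, (xtr, ytr), (xva, yva), config)
    result = evaluate(model, (xte, yte), classes, spec.scenario, scheme)
    return result, history
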