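"""Synthetic labeled enhancer-like sequence generator.

Emulates the shape of a curated enhancer corpus — 2 or 3 classes
(human enhancer / mouse enhancer / optionally no enhancer), variable
sequence lengths of at least a thousand bases — by drawing each position
i.i.d. from a class-specific nucleotide composition. Composition is the
only class signal, which is exactly the feature family the in-scope
encodings can see; no motif grammar, dinucleotide structure or
conservation is simulated.

The separability presets fix study conditions for pipeline tests:

* ``strong`` — compositions differ by >= 0.15 in at least two bases AND
  have distinct sums of squared base frequencies, so the dynamic
  base-frequency encoding separates classes by per-position value alone.
  (Permuting one composition into another would leave that value
  distribution unchanged, hence the presets avoid pure permutations.)
* ``moderate`` — the same directions of difference at half the magnitude.
* ``none`` — identical compositions: a null dataset on which any honest
  classifier sits at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import CANONICAL_BASES, LabeledDataset, NucleotideSequence

DEFAULT_CLASS_NAMES = ("human_enhancer", "mouse_enhancer", "no_enhancer")

_PRESET_COMPOSITIONS = {
    # base order A, C, G, T
    "strong": [
        (0.40, 0.40, 0.10, 0.10),
        (0.25, 0.25, 0.25, 0.25),
        (0.10, 0.55, 0.25, 0.10),
    ],
    "moderate": [
        (0.325, 0.325, 0.175, 0.175),
        (0.25, 0.25, 0.25, 0.25),
        (0.175, 0.40, 0.25, 0.175),
    ],
    "none": [
        (0.25, 0.25, 0.25, 0.25),
        (0.25, 0.25, 0.25, 0.25),
        (0.25, 0.25, 0.25, 0.25),
    ],
}


@dataclass
class SyntheticDatasetConfig:
    """Recipe for one labeled synthetic dataset."""

    n_classes: int
    compositions: list[tuple[float, float, float, float]]
    length_range: tuple[int, int] = (1000, 3000)
    n_per_class: int = 300
    seed: int = 0
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if len(self.compositions) != self.n_classes:
            raise ValueError(
                f"need {self.n_classes} composition vectors, got {len(self.compositions)}"
            )
        for comp in self.compositions:
            arr = np.asarray(comp, dtype=float)
            if arr.shape != (4,):
                raise ValueError(f"composition must have 4 entries, got {comp}")
            if (arr < 0).any() or not np.isclose(arr.sum(), 1.0, atol=1e-9):
                raise ValueError(f"composition must be non-negative and sum to 1, got {comp}")
            if np.count_nonzero(arr) == 0:
                raise ValueError("degenerate (all-zero) composition")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not self.class_names:
            self.class_names = list(DEFAULT_CLASS_NAMES[: self.n_classes])
        if len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")


def generate_dataset(config: SyntheticDatasetConfig) -> LabeledDataset:
    """Draw the dataset: per class, i.i.d. positions from its composition.

    Lengths are uniform integers on ``length_range`` (inclusive).
    Deterministic for a given config (one seeded generator drives lengths
    and residues in a fixed class-by-class order).
    """
    rng = np.random.default_rng(config.seed)
    bases = np.frombuffer(CANONICAL_BASES.encode(), dtype="S1").astype("U1")
    sequences = []
    for name, comp in zip(config.class_names, config.compositions):
        p = np.asarray(comp, dtype=float)
        p = p / p.sum()
        lo, hi = config.length_range
        for i in range(config.n_per_class):
            length = int(rng.integers(lo, hi + 1))
            residues = "".join(rng.choice(bases, size=length, p=p))
            sequences.append(
                NucleotideSequence(id=f"{name}_{i:05d}", residues=residues, label=name)
            )
    return LabeledDataset(sequences, provenance=f"synthetic seed={config.seed}")


def preset_separable(
    level: str,
    n_classes: int = 2,
    n_per_class: int = 300,
    length_range: tuple[int, int] = (1000, 3000),
    seed: int = 0,
) -> SyntheticDatasetConfig:
    """A ready-made config at a named separability level.

    ``strong`` class compositions differ by at least 0.15 in two or more
    bases; ``none`` uses identical compositions (the chance-level null).
    """
    if level not in _PRESET_COMPOSITIONS:
        raise ValueError(f"unknown level {level!r}; choose from {sorted(_PRESET_COMPOSITIONS)}")
    comps = _PRESET_COMPOSITIONS[level][:n_classes]
    return SyntheticDatasetConfig(
        n_classes=n_classes,
        compositions=[tuple(c) for c in comps],
        length_range=length_range,
        n_per_class=n_per_class,
        seed=seed,
    )
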