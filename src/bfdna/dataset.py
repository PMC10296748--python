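"""Core sequence containers shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

CANONICAL_BASES = "ACGT"

# IUPAC single-letter ambiguity codes beyond A/C/G/T
AMBIGUITY_CODES = set("RYSWKMBDHVN")


class SequenceValidationError(ValueError):
    """Raised when a nucleotide string fails strict validation."""


@dataclass
class NucleotideSequence:
    """An identified DNA string with an optional class label.

    Residues are upper-cased on construction; FASTA files routinely mix
    soft-masked lower case with upper case and the encodings are
    case-insensitive by design.
    """

    id: str
    residues: str
    label: str | None = None

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)

    def validate(self, strict: bool = True) -> "NucleotideSequence":
        """Check residues; in strict mode only A/C/G/T are admitted.

        Lenient mode additionally allows IUPAC ambiguity codes, which the
        encodings later map to a neutral pad value.
        """
        if not self.residues:
            raise SequenceValidationError(f"sequence {self.id!r} is empty")
        allowed = set(CANONICAL_BASES) if strict else set(CANONICAL_BASES) | AMBIGUITY_CODES
        for pos, sym in enumerate(self.residues):
            if sym not in allowed:
                raise SequenceValidationError(
                    f"sequence {self.id!r}: invalid symbol {sym!r} at position {pos}"
                )
        return self


@dataclass
class LabeledDataset:
    """An ordered collection of labelled sequences with unique ids."""

    sequences: list[NucleotideSequence] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for seq in self.sequences:
            if seq.id in seen:
                raise ValueError(f"duplicate sequence id {seq.id!r}")
            seen.add(seq.id)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[NucleotideSequence]:
        return iter(self.sequences)

    def __getitem__(self, idx: int) -> NucleotideSequence:
        return self.sequences[idx]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    @property
    def labels(self) -> list[str | None]:
        return [s.label for s in self.sequences]

    def label_universe(self) -> list[str]:
        """Sorted list of distinct labels (alphabetical class order)."""
        return sorted({s.label for s in self.sequences if s.label is not None})

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.sequences[i] for i in indices], provenance=self.provenance)
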