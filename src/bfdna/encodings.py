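"""Numeric DNA encodings: three static per-base schemes and the dynamic
base-repetition-frequency scheme (BFDNA).

The static schemes substitute a fixed number for each base:

* ``integer`` — arbitrary integers A=1, C=3, G=2, T=4;
* ``atomic``  — atomic-number indicators A=70, C=58, G=78, T=66;
* ``eiip``    — electron-ion interaction potentials A=0.1260, C=0.1340,
  G=0.0806, T=0.1335.

BFDNA is dynamic: position *i* takes the relative frequency
``count(base_i) / len(sequence)`` of its own base within that sequence, so
the number assigned to, say, C depends on the whole sequence. It is the
term-frequency idea from text processing transplanted to the 4-letter DNA
alphabet.

Also provided: min-max normalization against scheme-level bounds and
fixed-length padding/truncation, the two preprocessing steps that sit
between raw encodings and recurrent-model input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .dataset import CANONICAL_BASES, NucleotideSequence, SequenceValidationError

SCHEMES = ("integer", "atomic", "eiip", "bfdna")

INTEGER_MAP = {"A": 1.0, "C": 3.0, "G": 2.0, "T": 4.0}
ATOMIC_MAP = {"A": 70.0, "C": 58.0, "G": 78.0, "T": 66.0}
EIIP_MAP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}

#: Theoretical alphabet extremes per scheme, used as min-max bounds so that
#: normalization is deterministic and identical across train/test splits.
SCHEME_BOUNDS: dict[str, tuple[float, float]] = {
    "integer": (1.0, 4.0),
    "atomic": (58.0, 78.0),
    "eiip": (0.0806, 0.1340),
    "bfdna": (0.0, 1.0),
}


@dataclass
class EncodedSequence:
    """A numeric vector produced by one scheme from one sequence."""

    values: np.ndarray
    scheme: str
    source_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BaseFrequencyTable:
    """Relative frequency of each canonical base within one sequence."""

    freq_A: float
    freq_C: float
    freq_G: float
    freq_T: float

    def as_dict(self) -> dict[str, float]:
        return {"A": self.freq_A, "C": self.freq_C, "G": self.freq_G, "T": self.freq_T}

    def __getitem__(self, base: str) -> float:
        return self.as_dict()[base]


def _substitute(
    seq: NucleotideSequence, mapping: dict[str, float], scheme: str, strict: bool, pad_value: float
) -> EncodedSequence:
    seq.validate(strict=strict)
    values = np.fromiter(
        (mapping.get(sym, pad_value) for sym in seq.residues), dtype=float, count=len(seq)
    )
    return EncodedSequence(values=values, scheme=scheme, source_id=seq.id)


def encode_integer(seq: NucleotideSequence, strict: bool = True, pad_value: float = 0.0) -> EncodedSequence:
    """Integer scheme: A→1, C→3, G→2, T→4."""
    return _substitute(seq, INTEGER_MAP, "integer", strict, pad_value)


def encode_atomic(seq: NucleotideSequence, strict: bool = True, pad_value: float = 0.0) -> EncodedSequence:
    """Atomic-number scheme: A→70, C→58, G→78, T→66."""
    return _substitute(seq, ATOMIC_MAP, "atomic", strict, pad_value)


def encode_eiip(seq: NucleotideSequence, strict: bool = True, pad_value: float = 0.0) -> EncodedSequence:
    """EIIP scheme: A→0.1260, C→0.1340, G→0.0806, T→0.1335."""
    return _substitute(seq, EIIP_MAP, "eiip", strict, pad_value)


def base_frequencies(seq: NucleotideSequence, strict: bool = True) -> BaseFrequencyTable:
    """Relative frequency of each canonical base: count / total length.

    In lenient mode ambiguity codes are excluded from the numerators but kept
    in the length denominator, so the four entries sum to less than 1 when
    such codes are present.
    """
    seq.validate(strict=strict)
    if len(seq) == 0:
        raise SequenceValidationError(f"sequence {seq.id!r} is empty")
    counts = Counter(seq.residues)
    n = len(seq)
    return BaseFrequencyTable(*(counts.get(b, 0) / n for b in CANONICAL_BASES))


def encode_bfdna(seq: NucleotideSequence, strict: bool = True, pad_value: float = 0.0) -> EncodedSequence:
    """BFDNA scheme: position i carries the whole-sequence frequency of base i.

    Dynamic by construction — the value of a base is count/length within this
    sequence, so identical bases encode differently across sequences.
    """
    table = base_frequencies(seq, strict=strict).as_dict()
    return _substitute(seq, table, "bfdna", strict=False, pad_value=pad_value)


_ENCODERS = {
    "integer": encode_integer,
    "atomic": encode_atomic,
    "eiip": encode_eiip,
    "bfdna": encode_bfdna,
}


def encode(seq: NucleotideSequence, scheme: str, strict: bool = True, pad_value: float = 0.0) -> EncodedSequence:
    """Dispatch to one of the four schemes by name."""
    try:
        encoder = _ENCODERS[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}") from None
    return encoder(seq, strict=strict, pad_value=pad_value)


def minmax_normalize(encoded: EncodedSequence, bounds: tuple[float, float] | None = None) -> EncodedSequence:
    """Map values through (v - min) / (max - min) using scheme-level bounds.

    Bounds default to the scheme's theoretical alphabet extremes
    (``SCHEME_BOUNDS``), making the transform independent of any particular
    dataset and therefore leak-free across splits.
    """
    lo, hi = bounds if bounds is not None else SCHEME_BOUNDS[encoded.scheme]
    if not lo < hi:
        raise ValueError(f"degenerate bounds ({lo}, {hi}): min must be < max")
    return EncodedSequence(
        values=(encoded.values - lo) / (hi - lo), scheme=encoded.scheme, source_id=encoded.source_id
    )


def pad_or_truncate(encoded: EncodedSequence, target_length: int, pad_value: float = 0.0) -> EncodedSequence:
    """Force a fixed length: truncate keeping the 5' prefix, or pad at the 3' end."""
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    v = encoded.values
    if len(v) >= target_length:
        out = v[:target_length].copy()
    else:
        out = np.full(target_length, pad_value, dtype=float)
        out[: len(v)] = v
    return EncodedSequence(values=out, scheme=encoded.scheme, source_id=encoded.source_id)


def encode_matrix(
    sequences: list[NucleotideSequence],
    scheme: str,
    input_length: int,
    strict: bool = True,
    normalize: bool = True,
    pad_value: float = 0.0,
) -> np.ndarray:
    """Encode, normalize and fix the length of many sequences at once.

    Returns an (n_sequences, input_length) float matrix ready for model
    input. BFDNA frequencies are always computed on the full, un-truncated
    sequence; only the numeric vector is windowed.
    """
    rows = []
    for seq in sequences:
        enc = encode(seq, scheme, strict=strict, pad_value=pad_value)
        if normalize:
            enc = minmax_normalize(enc)
        enc = pad_or_truncate(enc, input_length, pad_value=pad_value)
        rows.append(enc.values)
    return np.stack(rows) if rows else np.empty((0, input_length))
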