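import numpy as np
import pytest

from bfdna import LabeledDataset, NucleotideSequence


@pytest.fixture
def worked_example():
    """The 10-mer used throughout the encoding worked examples."""
    return NucleotideSequence("ex", "ACACCCAGGT")


@pytest.fixture
def five_mers():
    """The two 5-mers whose four encodings are tabulated side by side."""
    return (
        NucleotideSequence("first", "CATCG"),
        NucleotideSequence("second", "CGAAT"),
    )


@pytest.fixture
def small_dataset():
    rng = np.random.default_rng(42)
    seqs = []
    for label, n in (("human_enhancer", 30), ("mouse_enhancer", 30)):
        for i in range(n):
            residues = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 120))))
            seqs.append(NucleotideSequence(f"{label}_{i}", residues, label=label))
    return LabeledDataset(seqs)
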