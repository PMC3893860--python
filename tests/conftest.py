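import numpy as np
import pytest

from il4kit.peptide_io import Peptide, PeptideDataset
from il4kit.synthetic_data import default_benchmark_scenario, generate


def make_dataset(seqs, label="unlabeled", prefix="p"):
    return PeptideDataset(
        [Peptide(f"{prefix}{i}", s, label) for i, s in enumerate(seqs)]
    )


def random_peptide(rng, length=None, lo=8, hi=22):
    from il4kit.alphabet import AMINO_ACIDS

    if length is None:
        length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def bench_data():
    """The canonical seeded benchmark datasets (500 + 500 peptides)."""
    return generate(default_benchmark_scenario())


@pytest.fixture
def toy_pos():
    return make_dataset(["KKKKKKKK"] * 10, "positive", "pos")


@pytest.fixture
def toy_neg():
    return make_dataset(["GGGGGGGG"] * 10, "negative", "neg")
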