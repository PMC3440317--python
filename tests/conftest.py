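import numpy as np
import pytest

import tripitope as tp


@pytest.fixture(scope="session")
def blosum62():
    return tp.load_substitution_matrix("blosum62")


@pytest.fixture(scope="session")
def pam160():
    return tp.load_substitution_matrix("pam160")


@pytest.fixture(scope="session")
def small_benchmark():
    """A small planted-signal dataset shared by model-level tests."""
    dataset, background, spec = tp.benchmark_dataset(n_per_class=150, L=20, seed=7)
    return dataset, background


@pytest.fixture(scope="session")
def small_model(small_benchmark):
    dataset, background = small_benchmark
    return tp.fit_full_model(dataset, background)


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(tp.AMINO_ACIDS), size=length))
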