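import numpy as np
import pytest

from qmdr import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, n, m, trait_kind="quantitative"):
    """Unstructured dataset: independent genotypes, trait unrelated to them."""
    geno = rng.integers(0, 3, size=(n, m))
    if trait_kind == "binary":
        trait = np.zeros(n, dtype=np.int64)
        trait[: n // 2] = 1
        rng.shuffle(trait)
    else:
        trait = rng.standard_normal(n)
    return Dataset(geno, trait, tuple(f"SNP{i+1}" for i in range(m)), trait_kind)


@pytest.fixture
def tiny_binary_dataset():
    geno = np.array([[0, 1], [2, 0], [1, 1], [0, 0]])
    trait = np.array([0, 1, 0, 1])
    return Dataset(geno, trait, ("SNP1", "SNP2"), "binary")
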