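import numpy as np
import pytest
from hypothesis import settings

from abcorigin import synthetic_data

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tree():
    return synthetic_data.default_tree()


@pytest.fixture(scope="session")
def template():
    return synthetic_data.StudyTemplate.default()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence_panel(rng, n_pops=3, max_n=8, max_sites=20):
    """Small random aligned panel with occasional missing symbols."""
    from abcorigin.formats_io import SequencePanel

    L = int(rng.integers(2, max_sites + 1))
    sizes = [int(rng.integers(2, max_n + 1)) for _ in range(n_pops)]
    alphabet = np.array(list("ACGT"))
    seqs, pops, ids = [], [], []
    k = 0
    for p, size in enumerate(sizes):
        for _ in range(size):
            chars = alphabet[rng.integers(0, 4, L)].tolist()
            for j in range(L):  # sprinkle missing data
                if rng.random() < 0.05:
                    chars[j] = "N" if rng.random() < 0.5 else "-"
            seqs.append("".join(chars))
            pops.append(f"P{p}")
            ids.append(f"s{k}")
            k += 1
    return SequencePanel(ids, pops, seqs, L)


def random_str_panel(rng, n_pops=3, max_n=8, n_loci=5):
    from abcorigin.formats_io import MISSING_REPEAT, STRPanel

    sizes = [int(rng.integers(2, max_n + 1)) for _ in range(n_pops)]
    n = sum(sizes)
    repeats = rng.integers(8, 16, size=(n, n_loci))
    miss = rng.random((n, n_loci)) < 0.05
    repeats[miss] = MISSING_REPEAT
    pops = [f"P{p}" for p, size in enumerate(sizes) for _ in range(size)]
    ids = [f"s{i}" for i in range(n)]
    return STRPanel(ids, pops, [f"L{j}" for j in range(n_loci)], repeats)
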