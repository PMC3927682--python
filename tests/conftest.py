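import numpy as np
import pytest

import grammap as gm


@pytest.fixture(scope="session")
def toy_index():
    """Index of the 8bp toy sequence used in the gram-counting examples."""
    seqs = gm.place_sequences([("chr1", "ACCTACCT")])
    return gm.build_index(seqs, 3)


@pytest.fixture(scope="session")
def small_genome():
    return gm.random_genome(2000, 1, seed=42)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return gm.build_index(small_genome, 6)


def brute_hamming_starts(oriented_read: str, text: str, k: int) -> list[int]:
    """All window starts of ``text`` within Hamming distance k (independent scan)."""
    m = len(oriented_read)
    if m > len(text):
        return []
    arr = np.frombuffer(text.encode(), dtype=np.uint8)
    r = np.frombuffer(oriented_read.encode(), dtype=np.uint8)
    n_win = len(text) - m + 1
    mism = np.zeros(n_win, dtype=np.int64)
    for i in range(m):
        mism += arr[i : i + n_win] != r[i]
    return [int(p) for p in np.flatnonzero(mism <= k)]


def brute_gram_positions(text: str, gram: str) -> list[int]:
    """Window-scan positions of ``gram`` in ``text``."""
    q = len(gram)
    return [i for i in range(len(text) - q + 1) if text[i : i + q] == gram]
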