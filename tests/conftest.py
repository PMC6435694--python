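import numpy as np
import pandas as pd
import pytest

from neuropep import Peptide


@pytest.fixture
def toy_peptides():
    return [
        Peptide("p1", "ACDEFGHIKL"),
        Peptide("p2", "AAAAACCCCC"),
        Peptide("p3", "GGGGGAAAAA"),
    ]


@pytest.fixture
def separable_toy():
    """20 points in 2-D, positives at (1,0)-ish, negatives at (0,1)-ish."""
    rng = np.random.default_rng(42)
    pos = rng.normal([1.0, 0.0], 0.05, size=(10, 2))
    neg = rng.normal([0.0, 1.0], 0.05, size=(10, 2))
    X = pd.DataFrame(np.vstack([pos, neg]), columns=["f1", "f2"])
    y = np.array([1] * 10 + [0] * 10)
    return X, y


def random_peptides(n, rng, min_len=5, max_len=80, prefix="r"):
    """Uniform random peptides for oracle comparisons."""
    from neuropep import AMINO_ACIDS

    letters = list(AMINO_ACIDS)
    out = []
    for i in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        out.append(Peptide(f"{prefix}{i}", "".join(rng.choice(letters, L))))
    return out
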