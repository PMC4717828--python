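import numpy as np
import pytest

from triadpc import MISSING, TrioGenotypes


def random_trios(rng, n_trios, n_loci, missing_rate=0.0):
    """Mendelian-consistent random trios, optionally with missing cells."""
    p = rng.uniform(0.2, 0.8, n_loci)
    m1, m2, f1, f2 = (rng.random((4, n_trios, n_loci)) < p).astype(int)
    tm = np.where(rng.random((n_trios, n_loci)) < 0.5, m1, m2)
    tf = np.where(rng.random((n_trios, n_loci)) < 0.5, f1, f2)
    M, F, C = m1 + m2, f1 + f2, tm + tf
    if missing_rate > 0:
        M = np.where(rng.random(M.shape) < missing_rate, MISSING, M)
        F = np.where(rng.random(F.shape) < missing_rate, MISSING, F)
        C = np.where(rng.random(C.shape) < missing_rate, MISSING, C)
    return TrioGenotypes(M=M, F=F, C=C)


@pytest.fixture
def rng():
    return np.random.default_rng(20160119)


@pytest.fixture
def small_trios(rng):
    return random_trios(rng, n_trios=50, n_loci=5)
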