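import numpy as np
import pytest
from hypothesis import settings

from blockalign import NEG_INF, Pssm, make_dna_scheme, load_blosum62

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")

DNA_LETTERS = list("ACGT")
AA_LETTERS = list("ARNDCQEGHILKMFPSTWYV")


@pytest.fixture(scope="session")
def dna24():
    """minimap2-style DNA scheme: match 2, mismatch -4."""
    return make_dna_scheme(2, -4)


@pytest.fixture(scope="session")
def blosum62():
    return load_blosum62()


def random_seq(rng, n, letters=DNA_LETTERS):
    return "".join(rng.choice(letters, size=n))


def naive_gotoh(q: str, pssm: Pssm):
    """Independent triple-loop reference for the generalized recurrence.

    Pure-Python, full matrices, no vectorization or blocks; returns
    (global score, max computed D with its position).
    """
    nq, npp = len(q), len(pssm)
    g = pssm.gaps
    ge = int(g.g_ext)
    qi = pssm.alphabet.encode(q)
    prof = pssm.profile_scores
    D = [[NEG_INF] * (npp + 1) for _ in range(nq + 1)]
    C = [[NEG_INF] * (npp + 1) for _ in range(nq + 1)]
    R = [[NEG_INF] * (npp + 1) for _ in range(nq + 1)]
    Dp = [[NEG_INF] * (npp + 1) for _ in range(nq + 1)]
    D[0][0] = Dp[0][0] = 0
    best, best_pos = 0, (0, 0)
    for i in range(nq + 1):
        for j in range(npp + 1):
            if i == 0 and j == 0:
                continue
            c = (max(C[i][j - 1] + ge, D[i][j - 1] + int(g.g_open_c[j]) + ge)
                 if j > 0 else NEG_INF)
            diag = (D[i - 1][j - 1] + int(prof[j - 1, qi[i - 1]])
                    if i > 0 and j > 0 else NEG_INF)
            dp = max(diag, c + int(g.g_close_c[j]) if j > 0 else NEG_INF)
            r = (max(R[i - 1][j] + ge, Dp[i - 1][j] + int(g.g_open_r[j]) + ge)
                 if i > 0 else NEG_INF)
            C[i][j], R[i][j], Dp[i][j] = c, r, dp
            D[i][j] = max(dp, r)
            if D[i][j] > best:
                best, best_pos = D[i][j], (i, j)
    return D[nq][npp], (best, best_pos)
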