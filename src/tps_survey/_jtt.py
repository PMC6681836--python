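"""Jones-Taylor-Thornton (JTT) amino acid replacement model.

The exchangeability lower triangle and equilibrium frequencies below are the
published JTT values (Jones, Taylor & Thornton 1992) in the conventional
ARNDCQEGHILKMFPSTWYV residue order, as redistributed by standard
phylogenetics software. The instantaneous rate matrix Q is built as
Q[i, j] = s[i, j] * pi[j] (i != j), diagonal set so rows sum to zero, and the
whole matrix scaled so the expected number of substitutions per site per unit
time is 1.
"""

from __future__ import annotations

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

# Lower triangle of the symmetric exchangeability matrix, row by row
# (row r covers pairs (r, 0..r-1) for r = 1..19).
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]

JTT_FREQS = np.array([
    0.0767479232521, 0.0516909483091, 0.0426449573550, 0.0515439484561,
    0.0198029801970, 0.0407519592480, 0.0618299381701, 0.0731519268481,
    0.0229439770560, 0.0537609462391, 0.0919039080961, 0.0586759413241,
    0.0238259761740, 0.0401259598740, 0.0509009490991, 0.0687649312351,
    0.0585649414351, 0.0142609857390, 0.0321019678980, 0.0660049339951,
])


def _build_rate_matrix() -> np.ndarray:
    s = np.zeros((20, 20))
    k = 0
    for r in range(1, 20):
        for c in range(r):
            s[r, c] = s[c, r] = _JTT_LOWER[k]
            k += 1
    q = s * JTT_FREQS[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    # normalize to 1 expected substitution per site per unit time
    mu = -(JTT_FREQS * np.diag(q)).sum()
    return q / mu


JTT_Q = _build_rate_matrix()

# Spectral decomposition of the reversible Q for fast transition matrices:
# B = D^{1/2} Q D^{-1/2} is symmetric; P(t) = D^{-1/2} U exp(L t) U^T D^{1/2}.
_sqrt_pi = np.sqrt(JTT_FREQS)
_B = (_sqrt_pi[:, None] * JTT_Q) / _sqrt_pi[None, :]
_eigval, _eigvec = np.linalg.eigh((_B + _B.T) / 2.0)
_left = _sqrt_pi[:, None] * _eigvec          # D^{1/2} U
_right = (_eigvec / _sqrt_pi[:, None]).T     # U^T D^{-1/2}, transposed later


def transition_matrix(t: float) -> np.ndarray:
    """P(t) = exp(Q t); rows sum to 1, P(0) = I."""
    if t < 0:
        raise ValueError("time must be non-negative")
    p = (_eigvec / _sqrt_pi[:, None]) @ (np.exp(_eigval * t)[:, None] * (_eigvec.T * _sqrt_pi[None, :]))
    return np.clip(p, 0.0, None)
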