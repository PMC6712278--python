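"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the alignment oracle
is a hand-written Gotoh dynamic program, the ANOVA oracle builds dummy
matrices and residual sums of squares with bare numpy least squares, and
the BH oracle enumerates every candidate k of the step-up rule.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from scipy.stats import f as f_dist

_B62 = substitution_matrices.load("BLOSUM62")


def sw_affine_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Smith–Waterman optimal local score with affine gaps (full DP).

    A gap of length k costs ``gap_open + k * gap_extend``, so opening a
    gap charges ``gap_open + gap_extend`` and each further residue
    ``gap_extend``.
    """
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (a consumed)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a (b consumed)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i, j] = max(
                0.0,
                M[i - 1, j - 1] + s,
                Ix[i - 1, j - 1] + s,
                Iy[i - 1, j - 1] + s,
            )
            Ix[i, j] = max(
                M[i - 1, j] - gap_open - gap_extend,
                Ix[i - 1, j] - gap_extend,
            )
            Iy[i, j] = max(
                M[i, j - 1] - gap_open - gap_extend,
                Iy[i, j - 1] - gap_extend,
            )
            best = max(best, M[i, j])
    return best


def enumerate_short_local(a: str, b: str) -> float:
    """Best gapless local alignment score over all start pairs and lengths.

    Exhaustive for short sequences; with no gaps allowed this enumerates
    every local alignment of length <= min(len(a), len(b)) plus the empty
    alignment (score 0).
    """
    best = 0.0
    for i in range(len(a)):
        for j in range(len(b)):
            total = 0.0
            for k in range(min(len(a) - i, len(b) - j)):
                total += _B62[a[i + k], b[j + k]]
                best = max(best, total)
    return best


def bh_flags_bruteforce(pvals, q: float = 0.05) -> np.ndarray:
    """BH step-up flags by checking every candidate k explicitly."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    best_k = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * q / m:
            best_k = k
    flags = np.zeros(m, dtype=bool)
    flags[order[:best_k]] = True
    return flags


def _dummies(levels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns for a categorical vector (drop first)."""
    uniq = sorted(set(levels))
    return np.column_stack([(levels == u).astype(float) for u in uniq[1:]]) \
        if len(uniq) > 1 else np.zeros((len(levels), 0))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def anova_type2_oracle(y: np.ndarray, factors: dict[str, np.ndarray]) -> dict[str, tuple[float, float]]:
    """Type II main-effects F and p per factor via explicit RSS differences."""
    n = len(y)
    blocks = {name: _dummies(np.asarray(vals)) for name, vals in factors.items()}
    X_full = np.column_stack([np.ones(n)] + [blocks[k] for k in factors])
    rss_full = _rss(X_full, y)
    df_resid = n - np.linalg.matrix_rank(X_full)
    out = {}
    for name in factors:
        X_red = np.column_stack(
            [np.ones(n)] + [blocks[k] for k in factors if k != name]
        )
        df_f = np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_red)
        rss_red = _rss(X_red, y)
        F = ((rss_red - rss_full) / df_f) / (rss_full / df_resid)
        p = float(f_dist.sf(F, df_f, df_resid))
        out[name] = (float(F), p)
    return out
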