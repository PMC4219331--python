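"""Jit-compiled affine-gap alignment kernels.

Gap convention: a gap of length L costs ``gap_open + L * gap_extend`` (both
negative), i.e. a separate existence penalty plus a per-residue extension —
the convention behind the usual -11/-1 protein defaults. ``E`` holds
gap-in-the-second-sequence (horizontal) states, ``F`` gap-in-the-first
(vertical) states.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Sentinel for unreachable affine states; large enough to survive additions.
NEG = -(1 << 40)


@njit(cache=True)
def sw_fill(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    """Fill local-alignment DP matrices; returns (H, E, F, best, bi, bj).

    ``best`` is the optimal local score (floored at 0) and ``(bi, bj)`` the
    first best cell in row-major order (strict improvement only), which
    fixes the reported optimum when ties exist.
    """
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), np.int64)
    E = np.full((n + 1, m + 1), NEG, np.int64)
    F = np.full((n + 1, m + 1), NEG, np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] + gap_open + gap_extend
            t = E[i, j - 1] + gap_extend
            if t > e:
                e = t
            E[i, j] = e
            f = H[i - 1, j] + gap_open + gap_extend
            t = F[i - 1, j] + gap_extend
            if t > f:
                f = t
            F[i, j] = f
            v = H[i - 1, j - 1] + sub[ai, b[j - 1]]
            if e > v:
                v = e
            if f > v:
                v = f
            if v < 0:
                v = 0
            H[i, j] = v
            if v > best:
                best = v
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def nw_score(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    """Global affine-gap optimum score (rolling rows; may be negative)."""
    n = a.shape[0]
    m = b.shape[0]
    h_prev = np.empty(m + 1, np.int64)
    f_prev = np.empty(m + 1, np.int64)
    h_cur = np.empty(m + 1, np.int64)
    f_cur = np.empty(m + 1, np.int64)
    h_prev[0] = 0
    f_prev[0] = NEG
    for j in range(1, m + 1):
        h_prev[j] = gap_open + gap_extend * j
        f_prev[j] = NEG
    for i in range(1, n + 1):
        ai = a[i - 1]
        h_cur[0] = gap_open + gap_extend * i
        f_cur[0] = NEG
        e = NEG
        for j in range(1, m + 1):
            f = h_prev[j] + gap_open + gap_extend
            t = f_prev[j] + gap_extend
            if t > f:
                f = t
            f_cur[j] = f
            e2 = h_cur[j - 1] + gap_open + gap_extend
            t = e + gap_extend
            if t > e2:
                e2 = t
            e = e2
            v = h_prev[j - 1] + sub[ai, b[j - 1]]
            if e > v:
                v = e
            if f > v:
                v = f
            h_cur[j] = v
        h_prev, h_cur = h_cur, h_prev
        f_prev, f_cur = f_cur, f_prev
    return h_prev[m]
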