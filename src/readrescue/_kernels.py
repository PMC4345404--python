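"""Numba-compiled dynamic-programming and scanning kernels.

These are the inner loops of the two aligners and of identity clustering.
Everything operates on uint8 code arrays from :mod:`readrescue._seq`; code 4
(N) never matches.  Traceback logic stays in Python (see callers) — the
kernels only fill matrices or count.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -(10**9)


@njit(cache=True)
def hamming_hits(genome, bounds, read, max_mm):
    """All end-to-end placements of ``read`` on the concatenated ``genome``
    with at most ``max_mm`` mismatches (single strand; caller handles the
    reverse complement).  ``bounds`` delimits chromosomes so placements never
    straddle two of them.  Returns (positions, mismatch counts)."""
    L = read.shape[0]
    total = 0
    for ci in range(bounds.shape[0] - 1):
        for s in range(bounds[ci], bounds[ci + 1] - L + 1):
            mm = 0
            for j in range(L):
                a = genome[s + j]
                if a != read[j] or a > 3:
                    mm += 1
                    if mm > max_mm:
                        break
            if mm <= max_mm:
                total += 1
    pos = np.empty(total, np.int64)
    mms = np.empty(total, np.int64)
    k = 0
    for ci in range(bounds.shape[0] - 1):
        for s in range(bounds[ci], bounds[ci + 1] - L + 1):
            mm = 0
            for j in range(L):
                a = genome[s + j]
                if a != read[j] or a > 3:
                    mm += 1
                    if mm > max_mm:
                        break
            if mm <= max_mm:
                pos[k] = s
                mms[k] = mm
                k += 1
    return pos, mms


@njit(cache=True)
def count_mismatches(genome, start, read):
    """Mismatches of an ungapped placement; N on either side mismatches."""
    mm = 0
    for j in range(read.shape[0]):
        a = genome[start + j]
        if a != read[j] or a > 3:
            mm += 1
    return mm


@njit(cache=True)
def sw_fill(read, ref, match, mismatch, gap_open, gap_extend):
    """Affine-gap local alignment matrices (Smith-Waterman-Gotoh).

    gap_open is the score of the first gapped base, gap_extend of each
    further base; both negative.  Returns H, pointer matrices and the
    position/value of the best cell (first maximum in row-major order, so
    tie-breaking is deterministic).
    Pointer codes in ``ptr``: 0 stop, 1 diagonal, 2 from E (gap consuming
    ref), 3 from F (gap consuming read).
    """
    m = read.shape[0]
    n = ref.shape[0]
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), NEG_INF, np.int32)
    F = np.full((m + 1, n + 1), NEG_INF, np.int32)
    ptr = np.zeros((m + 1, n + 1), np.uint8)
    ptrE = np.zeros((m + 1, n + 1), np.uint8)
    ptrF = np.zeros((m + 1, n + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
            a = read[i - 1]
            s = match if (a == ref[j - 1] and a <= 3) else mismatch
            d = H[i - 1, j - 1] + s
            h = 0
            p = 0
            if d > h:
                h = d
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return H, ptr, ptrE, ptrF, best, bi, bj


@njit(cache=True)
def _nw_match_count_packed(a, b):
    """nw_match_count fast path for sequences < 128 bp: (score, matches) is
    packed as score*128 + matches so the lexicographic max is a plain int
    max, and the DP uses two rolling rows."""
    m = a.shape[0]
    n = b.shape[0]
    prev = np.empty(n + 1, np.int32)
    cur = np.empty(n + 1, np.int32)
    for j in range(n + 1):
        prev[j] = -j * 128
    for i in range(1, m + 1):
        cur[0] = -i * 128
        for j in range(1, n + 1):
            if a[i - 1] == b[j - 1] and a[i - 1] <= 3:
                best = prev[j - 1] + 129  # +1 score, +1 match
            else:
                best = prev[j - 1] - 128
            s = prev[j] - 128
            if s > best:
                best = s
            s = cur[j - 1] - 128
            if s > best:
                best = s
            cur[j] = best
        tmp = prev
        prev = cur
        cur = tmp
    return prev[n] % 128


@njit(cache=True)
def _nw_match_count_big(a, b):
    m = a.shape[0]
    n = b.shape[0]
    S = np.empty((m + 1, n + 1), np.int32)
    M = np.zeros((m + 1, n + 1), np.int32)
    for j in range(n + 1):
        S[0, j] = -j
    for i in range(1, m + 1):
        S[i, 0] = -i
        for j in range(1, n + 1):
            hit = a[i - 1] == b[j - 1] and a[i - 1] <= 3
            sc = 1 if hit else -1
            best = S[i - 1, j - 1] + sc
            bm = M[i - 1, j - 1] + (1 if hit else 0)
            s = S[i - 1, j] - 1
            if s > best or (s == best and M[i - 1, j] > bm):
                best = s
                bm = M[i - 1, j]
            s = S[i, j - 1] - 1
            if s > best or (s == best and M[i, j - 1] > bm):
                best = s
                bm = M[i, j - 1]
            S[i, j] = best
            M[i, j] = bm
    return M[m, n]


@njit(cache=True)
def nw_match_count(a, b):
    """Matched positions in an optimal global (Needleman-Wunsch) alignment
    under match=+1, mismatch=-1, gap=-1.  Among score-optimal alignments the
    one with the most matches is counted (lexicographic DP), so the result
    is symmetric and independent of traceback order."""
    if a.shape[0] < 128 and b.shape[0] < 128:
        return _nw_match_count_packed(a, b)
    return _nw_match_count_big(a, b)
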