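"""Affine-gap dynamic-programming kernels (numba-jitted).

Scoring: match/mismatch substitution scores; a gap of length g costs
gap_open + (g - 1) * gap_extend.  Traceback prefers substitutions over
gaps on score ties, so reported identities are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10 ** 9)


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@njit(cache=False)
def _sw_kernel(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m, n = len(q), len(t)
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)
    F = np.full((m + 1, n + 1), NEG, np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            sub = match if q[i - 1] == t[j - 1] else mismatch
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback (diag preferred on ties)
    i, j = bi, bj
    matches = 0
    cols = 0
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            sub = match if q[i - 1] == t[j - 1] else mismatch
            if h == H[i - 1, j - 1] + sub:
                cols += 1
                if q[i - 1] == t[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            if E[i, j] == H[i, j - 1] + gap_open:
                state = 0
            j -= 1
        else:
            cols += 1
            if F[i, j] == H[i - 1, j] + gap_open:
                state = 0
            i -= 1
    return best, i, bi, j, bj, matches, cols


@njit(cache=False)
def _nw_free_kernel(q, t, match, mismatch, gap_open, gap_extend,
                    pad):  # pragma: no cover
    """Global alignment with free end gaps on both sequences, banded around
    the length-difference diagonal; pad >= len(q) + len(t) makes it exact."""
    m, n = len(q), len(t)
    b_lo = (m - n if m > n else 0) + pad
    b_hi = (n - m if n > m else 0) + pad
    if b_lo > m:
        b_lo = m
    if b_hi > n:
        b_hi = n
    W = b_lo + b_hi + 1
    H = np.full((m + 1, W), NEG, np.int32)
    E = np.full((m + 1, W), NEG, np.int32)
    F = np.full((m + 1, W), NEG, np.int32)
    for i in range(0, min(b_lo, m) + 1):  # j = 0 border (free leading q gap)
        H[i, b_lo - i] = 0
    for j in range(0, min(b_hi, n) + 1):  # i = 0 border
        H[0, j + b_lo] = 0
    for i in range(1, m + 1):
        j0 = i - b_lo if i - b_lo > 1 else 1
        j1 = i + b_hi if i + b_hi < n else n
        for j in range(j0, j1 + 1):
            k = j - i + b_lo
            e = NEG
            if k - 1 >= 0:
                e = H[i, k - 1] + gap_open
                e2 = E[i, k - 1] + gap_extend
                if e2 > e:
                    e = e2
            f = NEG
            if k + 1 < W:
                f = H[i - 1, k + 1] + gap_open
                f2 = F[i - 1, k + 1] + gap_extend
                if f2 > f:
                    f = f2
            sub = match if q[i - 1] == t[j - 1] else mismatch
            h = H[i - 1, k] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            E[i, k] = e
            F[i, k] = f
            H[i, k] = h
    # best cell on the terminal borders (free trailing gaps)
    best = NEG
    bi = m
    bj = n
    for k in range(W):
        j = k - b_lo + m
        if 0 <= j <= n and H[m, k] > best:
            best = H[m, k]
            bi = m
            bj = j
    for i in range(0, m + 1):
        k = n - i + b_lo
        if 0 <= k < W and H[i, k] > best:
            best = H[i, k]
            bi = i
            bj = n
    # traceback
    i, j = bi, bj
    matches = 0
    cols = 0
    state = 0
    while i > 0 and j > 0:
        k = j - i + b_lo
        if state == 0:
            sub = match if q[i - 1] == t[j - 1] else mismatch
            if H[i - 1, k] > NEG and H[i, k] == H[i - 1, k] + sub:
                cols += 1
                if q[i - 1] == t[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, k] == E[i, k]:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            if E[i, k] == H[i, k - 1] + gap_open:
                state = 0
            j -= 1
        else:
            cols += 1
            if F[i, k] == H[i - 1, k + 1] + gap_open:
                state = 0
            i -= 1
    return best, i, bi, j, bj, matches, cols


@njit(cache=False)
def _extend_kernel(q, t, match, mismatch, gap_open,
                   gap_extend):  # pragma: no cover
    """Gapped extension anchored at the origin: best-scoring alignment of a
    prefix of q against a prefix of t (no floor at zero, so extension stops
    where the score peaks).  Returns (best_i, best_j)."""
    m, n = len(q), len(t)
    H = np.full((m + 1, n + 1), NEG, np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)
    F = np.full((m + 1, n + 1), NEG, np.int32)
    H[0, 0] = 0
    best = 0
    bi = 0
    bj = 0
    for i in range(0, m + 1):
        for j in range(0, n + 1):
            if i == 0 and j == 0:
                continue
            e = NEG
            if j > 0:
                e = H[i, j - 1] + gap_open
                e2 = E[i, j - 1] + gap_extend
                if e2 > e:
                    e = e2
            f = NEG
            if i > 0:
                f = H[i - 1, j] + gap_open
                f2 = F[i - 1, j] + gap_extend
                if f2 > f:
                    f = f2
            h = NEG
            if i > 0 and j > 0:
                sub = match if q[i - 1] == t[j - 1] else mismatch
                h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return bi, bj


def extend_from_origin(query: str, target: str, match: int = 1,
                       mismatch: int = -2, gap_open: int = -2,
                       gap_extend: int = -1) -> tuple[int, int]:
    """How far an alignment anchored at position 0 of both sequences
    profitably extends; returns the (query, target) lengths consumed."""
    if not query or not target:
        return 0, 0
    bi, bj = _extend_kernel(encode(query), encode(target), match, mismatch,
                            gap_open, gap_extend)
    return int(bi), int(bj)


def smith_waterman(query: str, target: str, match: int = 1,
                   mismatch: int = -2, gap_open: int = -2,
                   gap_extend: int = -1) -> dict:
    """Best local alignment of query in target.

    Returns score, query/target spans, matched columns and total columns of
    the traceback path.
    """
    s, q0, q1, t0, t1, matches, cols = _sw_kernel(
        encode(query), encode(target), match, mismatch, gap_open, gap_extend)
    return {"score": int(s), "q_start": int(q0), "q_end": int(q1),
            "t_start": int(t0), "t_end": int(t1),
            "matches": int(matches), "columns": int(cols)}


def global_free_ends(query: str, target: str, match: int = 1,
                     mismatch: int = -2, gap_open: int = -2,
                     gap_extend: int = -1, band_pad: int | None = None) -> dict:
    """End-gap-free global alignment; identity excludes the end gaps.

    ``band_pad`` limits the search to a diagonal band around the length
    difference (None = exact, unbanded).
    """
    if band_pad is None:
        band_pad = len(query) + len(target)
    s, q0, q1, t0, t1, matches, cols = _nw_free_kernel(
        encode(query), encode(target), match, mismatch, gap_open, gap_extend,
        band_pad)
    return {"score": int(s), "q_start": int(q0), "q_end": int(q1),
            "t_start": int(t0), "t_end": int(t1),
            "matches": int(matches), "columns": int(cols),
            "identity": matches / cols if cols else 0.0}
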