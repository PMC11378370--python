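"""Numba dynamic-programming kernels for the two aligners.

Gap cost convention used throughout the package: a maximal gap run of
length k costs ``gap_open + k * gap_extend`` (both parameters negative).

``glocal_dp`` is the query-global / target-local ("glocal") affine-gap
aligner: the full query must appear in the alignment, unaligned target
ends are free.  ``profile_dp`` is a plain global affine-gap aligner over
frequency profiles, used by the progressive multiple aligner.

Move codes emitted by both tracebacks: 0 = aligned column (consumes one
position of each side), 1 = target/profile-B only (gap in query/A),
2 = query/A only (gap in target/B).  Moves are returned in alignment
order (left to right).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e18

_M, _I, _D = 0, 1, 2  # aligned / gap-in-query-row / gap-in-target-row


@njit(cache=True)
def glocal_dp(q, t, smat, gap_open, gap_ext):
    """Glocal affine alignment of encoded query q against target t.

    Returns (score, target_start, target_end, moves) with target
    coordinates 1-based inclusive over the consumed target region
    (target_start = target_end + 1 when no target base is consumed).
    """
    m = q.shape[0]
    n = t.shape[0]
    M = np.full((m + 1, n + 1), NEG)
    I = np.full((m + 1, n + 1), NEG)
    D = np.full((m + 1, n + 1), NEG)
    pM = np.zeros((m + 1, n + 1), dtype=np.int8)
    pI = np.zeros((m + 1, n + 1), dtype=np.int8)
    pD = np.zeros((m + 1, n + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for j in range(n + 1):
        I[0, j] = 0.0  # free unaligned target prefix

    for i in range(1, m + 1):
        # j == 0: only gaps in the target row are possible
        cm = M[i - 1, 0] + gap_open + gap_ext
        ci = I[i - 1, 0] + gap_open + gap_ext
        cd = D[i - 1, 0] + gap_ext
        if cm >= ci and cm >= cd:
            D[i, 0] = cm
            pD[i, 0] = _M
        elif cd >= ci:
            D[i, 0] = cd
            pD[i, 0] = _D
        else:
            D[i, 0] = ci
            pD[i, 0] = _I
        for j in range(1, n + 1):
            # aligned column
            s = smat[q[i - 1], t[j - 1]]
            am = M[i - 1, j - 1]
            ai = I[i - 1, j - 1]
            ad = D[i - 1, j - 1]
            if am >= ai and am >= ad:
                M[i, j] = am + s
                pM[i, j] = _M
            elif ad >= ai:
                M[i, j] = ad + s
                pM[i, j] = _D
            else:
                M[i, j] = ai + s
                pM[i, j] = _I
            # gap in the query row (consume target base)
            cm = M[i, j - 1] + gap_open + gap_ext
            ci = I[i, j - 1] + gap_ext
            cd = D[i, j - 1] + gap_open + gap_ext
            if cm >= ci and cm >= cd:
                I[i, j] = cm
                pI[i, j] = _M
            elif cd >= ci:
                I[i, j] = cd
                pI[i, j] = _D
            else:
                I[i, j] = ci
                pI[i, j] = _I
            # gap in the target row (consume query base)
            cm = M[i - 1, j] + gap_open + gap_ext
            ci = I[i - 1, j] + gap_open + gap_ext
            cd = D[i - 1, j] + gap_ext
            if cm >= ci and cm >= cd:
                D[i, j] = cm
                pD[i, j] = _M
            elif cd >= ci:
                D[i, j] = cd
                pD[i, j] = _D
            else:
                D[i, j] = ci
                pD[i, j] = _I

    # pick the best end column; ties resolved to the leftmost end, then
    # by state preference M > D > I, so results are deterministic
    best = NEG
    bj = 0
    bstate = _M
    for j in range(n + 1):
        for state in (_M, _D, _I):
            if state == _M:
                v = M[m, j]
            elif state == _D:
                v = D[m, j]
            else:
                v = I[m, j]
            if v > best:
                best = v
                bj = j
                bstate = state

    # traceback
    moves = np.empty(m + n, dtype=np.int8)
    k = 0
    i = m
    j = bj
    state = bstate
    while True:
        if i == 0 and (state == _I or (state == _M and j == 0)):
            break
        if state == _M:
            moves[k] = 0
            k += 1
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == _I:
            moves[k] = 1
            k += 1
            state = pI[i, j]
            j -= 1
        else:
            moves[k] = 2
            k += 1
            state = pD[i, j]
            i -= 1
    return best, j + 1, bj, moves[:k][::-1].copy()


@njit(cache=True)
def profile_dp(pa, pb, smat, gap_open, gap_ext):
    """Global affine alignment of two frequency profiles (La,5) x (Lb,5).

    Column score is the expected pairwise substitution score between the
    two profile columns (gap symbol index 4 scores 0 against everything).
    Returns (score, moves).
    """
    la = pa.shape[0]
    lb = pb.shape[0]
    # precompute column-vs-column scores
    colscore = np.zeros((la, lb))
    for i in range(la):
        for j in range(lb):
            s = 0.0
            for a in range(5):
                fa = pa[i, a]
                if fa == 0.0:
                    continue
                for b in range(5):
                    fb = pb[j, b]
                    if fb != 0.0:
                        s += fa * fb * smat[a, b]
            colscore[i, j] = s

    M = np.full((la + 1, lb + 1), NEG)
    I = np.full((la + 1, lb + 1), NEG)
    D = np.full((la + 1, lb + 1), NEG)
    pM = np.zeros((la + 1, lb + 1), dtype=np.int8)
    pI = np.zeros((la + 1, lb + 1), dtype=np.int8)
    pD = np.zeros((la + 1, lb + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for j in range(1, lb + 1):
        I[0, j] = gap_open + j * gap_ext
        pI[0, j] = _I
    for i in range(1, la + 1):
        D[i, 0] = gap_open + i * gap_ext
        pD[i, 0] = _D
        for j in range(1, lb + 1):
            s = colscore[i - 1, j - 1]
            am = M[i - 1, j - 1]
            ai = I[i - 1, j - 1]
            ad = D[i - 1, j - 1]
            if am >= ai and am >= ad:
                M[i, j] = am + s
                pM[i, j] = _M
            elif ad >= ai:
                M[i, j] = ad + s
                pM[i, j] = _D
            else:
                M[i, j] = ai + s
                pM[i, j] = _I
            cm = M[i, j - 1] + gap_open + gap_ext
            ci = I[i, j - 1] + gap_ext
            cd = D[i, j - 1] + gap_open + gap_ext
            if cm >= ci and cm >= cd:
                I[i, j] = cm
                pI[i, j] = _M
            elif cd >= ci:
                I[i, j] = cd
                pI[i, j] = _D
            else:
                I[i, j] = ci
                pI[i, j] = _I
            cm = M[i - 1, j] + gap_open + gap_ext
            ci = I[i - 1, j] + gap_open + gap_ext
            cd = D[i - 1, j] + gap_ext
            if cm >= ci and cm >= cd:
                D[i, j] = cm
                pD[i, j] = _M
            elif cd >= ci:
                D[i, j] = cd
                pD[i, j] = _D
            else:
                D[i, j] = ci
                pD[i, j] = _I

    best = M[la, lb]
    state = _M
    if D[la, lb] > best:
        best = D[la, lb]
        state = _D
    if I[la, lb] > best:
        best = I[la, lb]
        state = _I

    moves = np.empty(la + lb, dtype=np.int8)
    k = 0
    i = la
    j = lb
    while i > 0 or j > 0:
        if state == _M:
            moves[k] = 0
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == _I:
            moves[k] = 1
            state = pI[i, j]
            j -= 1
        else:
            moves[k] = 2
            state = pD[i, j]
            i -= 1
        k += 1
    return best, moves[:k][::-1].copy()
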