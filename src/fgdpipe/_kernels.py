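"""Numba inner loops for local alignment.

Affine gap convention follows BLAST: a gap of length L costs
gap_open + L * gap_extend.  Traceback tie-break is diagonal > up > left,
and among equal-scoring cells the one with the smallest (i, j) wins, so
alignments are byte-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1_000_000_000


@njit(cache=True)
def sw_affine(a, b, mat, gap_open, gap_extend, lo_diag, hi_diag):
    """Smith-Waterman with affine gaps, optionally banded.

    a, b : uint8-encoded sequences (row indices into ``mat``)
    lo_diag, hi_diag : only cells with lo_diag <= (i - j) <= hi_diag are
        computed (pass -len(b), len(a) for the full matrix).  Band
        restriction only removes paths, so the banded score never
        exceeds the full score.

    Returns (score, a_start, a_end, b_start, b_end, identities, aln_len)
    with 1-based inclusive coordinates of the aligned span; all zeros
    when the best score is 0.
    """
    m = len(a)
    n = len(b)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in a (left)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in b (up)
    go = gap_open + gap_extend
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        jlo = i - hi_diag
        if jlo < 1:
            jlo = 1
        jhi = i - lo_diag
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            e = E[i, j - 1] - gap_extend
            ho = H[i, j - 1] - go
            if ho > e:
                e = ho
            E[i, j] = e
            f = F[i - 1, j] - gap_extend
            vo = H[i - 1, j] - go
            if vo > f:
                f = vo
            F[i, j] = f
            h = H[i - 1, j - 1] + mat[a[i - 1], b[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback
    i = bi
    j = bj
    ident = 0
    alen = 0
    state = 0  # 0=H, 1=E (left), 2=F (up)
    go_ = go
    while True:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            diag = H[i - 1, j - 1] + mat[a[i - 1], b[j - 1]]
            if h == diag:
                if a[i - 1] == b[j - 1]:
                    ident += 1
                alen += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 2
            elif h == E[i, j]:
                state = 1
            else:  # pragma: no cover - unreachable
                break
        elif state == 2:  # gap in b, consuming a (up)
            alen += 1
            if F[i, j] == H[i - 1, j] - go_:
                i -= 1
                state = 0
            else:
                F_prev = F[i - 1, j]
                i -= 1
                state = 2 if F_prev != NEG else 0
        else:  # gap in a, consuming b (left)
            alen += 1
            if E[i, j] == H[i, j - 1] - go_:
                j -= 1
                state = 0
            else:
                E_prev = E[i, j - 1]
                j -= 1
                state = 1 if E_prev != NEG else 0
    return best, i + 1, bi, j + 1, bj, ident, alen


@njit(cache=True)
def xdrop_extend(ref, qry, r0, q0, wlen, match, mismatch, xdrop):
    """Extend an exact ``wlen``-mer match at (r0, q0) in both directions.

    Ungapped, score-based X-drop.  Returns (r_start, r_end, q_start,
    q_end, score, matches) with 0-based half-open ref/qry spans.
    """
    score = wlen * match
    matches = wlen
    # right extension
    best = score
    best_r = r0 + wlen
    best_q = q0 + wlen
    best_matches = matches
    cur = score
    curm = matches
    r = r0 + wlen
    q = q0 + wlen
    while r < len(ref) and q < len(qry):
        if ref[r] == qry[q]:
            cur += match
            curm += 1
        else:
            cur += mismatch
        r += 1
        q += 1
        if cur > best:
            best = cur
            best_r = r
            best_q = q
            best_matches = curm
        if best - cur > xdrop:
            break
    # left extension
    score = best
    matches = best_matches
    cur = best
    curm = matches
    best_l_r = r0
    best_l_q = q0
    r = r0
    q = q0
    while r > 0 and q > 0:
        r -= 1
        q -= 1
        if ref[r] == qry[q]:
            cur += match
            curm += 1
        else:
            cur += mismatch
        if cur > score:
            score = cur
            best_l_r = r
            best_l_q = q
            matches = curm
        if score - cur > xdrop:
            break
    return best_l_r, best_r, best_l_q, best_q, score, matches
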