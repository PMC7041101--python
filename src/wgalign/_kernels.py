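"""Numba-compiled hot loops: the LMEM scan and the affine-gap DP.

Both kernels work on the integer-coded alphabet from :mod:`wgalign.genome`
(1..4 = ACGT, anything else never matches).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# edit-operation codes shared with the aligner
OP_MATCH = 0
OP_MISMATCH = 1
OP_INS = 2  # consumes query
OP_DEL = 3  # consumes reference

_NEG = np.int32(-(10**9))


@njit(cache=True)
def scan_lmems(
    comp_codes,  # complement codes of the query, uint8
    counts,  # int64[8] cumulative symbol counts of the indexed text
    occ,  # int32[4, n+1] rank table over the BWT
    n_text,  # total text length
    k,  # minimum LMEM length
    f,  # maximum occurrence count (exclusive)
    sensitive,  # bool: restart at j1+stride instead of j2+1
    stride,  # restart offset in sensitive mode
    start,  # 0-based scan start (block left edge)
    end,  # 0-based last position allowed to start an LMEM (block right edge)
):
    """Scan one query block left to right, emitting LMEM seed candidates.

    The scan extends a match rightwards one query base at a time by prepending
    the base's complement to a backward search (the indexed text contains the
    reverse complement of the reference, so this finds forward-frame matches).
    Extension past ``end`` is permitted; only LMEMs starting at or before
    ``end`` are emitted.  Returns (j1, j2, lo, hi, starts, final_j): seed
    arrays (0-based inclusive), every scan start position visited, and the
    first scan position past ``end`` (where the scan would continue).
    """
    qlen = len(comp_codes)
    cap = 1024
    out_j1 = np.empty(cap, dtype=np.int64)
    out_j2 = np.empty(cap, dtype=np.int64)
    out_lo = np.empty(cap, dtype=np.int64)
    out_hi = np.empty(cap, dtype=np.int64)
    m = 0
    scap = 1024
    starts = np.empty(scap, dtype=np.int64)
    ns = 0

    j = start
    while j <= end:
        if ns == scap:
            scap *= 2
            tmp = np.empty(scap, dtype=np.int64)
            tmp[:ns] = starts[:ns]
            starts = tmp
        starts[ns] = j
        ns += 1
        lo = np.int64(0)
        hi = np.int64(n_text - 1)
        jj = j
        while jj < qlen:
            c = comp_codes[jj]
            if c < 1 or c > 4:
                break
            base = counts[c]
            nlo = base + occ[c - 1, lo]
            nhi = base + occ[c - 1, hi + 1] - 1
            if nlo > nhi:
                break
            lo = nlo
            hi = nhi
            jj += 1
        length = jj - j
        if length > 0:
            if length >= k and (hi - lo + 1) < f:
                if m == cap:
                    cap *= 2
                    tmp = np.empty(cap, dtype=np.int64)
                    tmp[:m] = out_j1[:m]
                    out_j1 = tmp
                    tmp = np.empty(cap, dtype=np.int64)
                    tmp[:m] = out_j2[:m]
                    out_j2 = tmp
                    tmp = np.empty(cap, dtype=np.int64)
                    tmp[:m] = out_lo[:m]
                    out_lo = tmp
                    tmp = np.empty(cap, dtype=np.int64)
                    tmp[:m] = out_hi[:m]
                    out_hi = tmp
                out_j1[m] = j
                out_j2[m] = jj - 1
                out_lo[m] = lo
                out_hi[m] = hi
                m += 1
            if sensitive:
                j = j + stride
            else:
                j = jj  # restart at the mismatch position (= j2 + 1)
        else:
            j += 1
    return out_j1[:m], out_j2[:m], out_lo[:m], out_hi[:m], starts[:ns], j


@njit(cache=True)
def gotoh_global(p, q, match, mismatch, gap_open, gap_extend, band=-1):
    """Global affine-gap alignment of two coded fragments (Gotoh).

    A gap of length L costs ``gap_open + L * gap_extend``.  Returns
    (score, ops) where ops is the per-column edit-operation array in
    left-to-right order (codes OP_*).  Tie-breaking is fixed for determinism:
    diagonal over deletion over insertion, and gap extension is preferred on
    ties so gaps open as far left as possible.  With ``band`` >= 0 only
    cells with |i - j| <= band are computed (the caller must ensure
    band >= |n - m| so a global path exists).
    """
    n = len(p)
    m = len(q)
    H = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap in query (deletion from P)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap in reference (insertion)
    # traceback: tb_h 0=diag,1=E,2=F ; tb_e/tb_f 0=open,1=extend
    tb_h = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tb_e = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tb_f = np.zeros((n + 1, m + 1), dtype=np.uint8)

    H[0, 0] = 0
    E[0, 0] = _NEG
    F[0, 0] = _NEG
    for i in range(1, n + 1):
        E[i, 0] = -(gap_open + gap_extend * i)
        H[i, 0] = E[i, 0]
        F[i, 0] = _NEG
        tb_h[i, 0] = 1
        tb_e[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        F[0, j] = -(gap_open + gap_extend * j)
        H[0, j] = F[0, j]
        E[0, j] = _NEG
        tb_h[0, j] = 2
        tb_f[0, j] = 1 if j > 1 else 0

    for i in range(1, n + 1):
        pc = p[i - 1]
        j_lo = 1
        j_hi = m
        if band >= 0:
            j_lo = max(1, i - band)
            j_hi = min(m, i + band)
        for j in range(j_lo, j_hi + 1):
            e_open = H[i - 1, j] - gap_open - gap_extend
            e_ext = E[i - 1, j] - gap_extend
            if e_ext >= e_open:
                E[i, j] = e_ext
                tb_e[i, j] = 1
            else:
                E[i, j] = e_open
                tb_e[i, j] = 0

            f_open = H[i, j - 1] - gap_open - gap_extend
            f_ext = F[i, j - 1] - gap_extend
            if f_ext >= f_open:
                F[i, j] = f_ext
                tb_f[i, j] = 1
            else:
                F[i, j] = f_open
                tb_f[i, j] = 0

            qc = q[j - 1]
            if pc == qc and pc >= 1 and pc <= 4:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] - mismatch
            best = diag
            tb = 0
            if E[i, j] > best:
                best = E[i, j]
                tb = 1
            if F[i, j] > best:
                best = F[i, j]
                tb = 2
            H[i, j] = best
            tb_h[i, j] = tb

    ops = np.empty(n + m, dtype=np.uint8)
    w = 0
    i = n
    j = m
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 or j > 0:
        if state == 0:
            t = tb_h[i, j]
            if t == 0:
                pc = p[i - 1]
                qc = q[j - 1]
                if pc == qc and pc >= 1 and pc <= 4:
                    ops[w] = OP_MATCH
                else:
                    ops[w] = OP_MISMATCH
                w += 1
                i -= 1
                j -= 1
            else:
                state = t
        elif state == 1:
            ops[w] = OP_DEL
            w += 1
            ext = tb_e[i, j]
            i -= 1
            state = 1 if ext == 1 else 0
        else:
            ops[w] = OP_INS
            w += 1
            ext = tb_f[i, j]
            j -= 1
            state = 2 if ext == 1 else 0
    return H[n, m], ops[:w][::-1].copy()
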