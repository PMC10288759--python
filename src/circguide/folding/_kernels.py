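"""Numba-jitted dynamic-programming fills for the builtin engines.

Matrix fills are the O(n^3) hot paths and run under numba; tracebacks
are cheap (O(n^2)) and live in plain Python next to the engines.  All
kernels take pre-encoded sequences (int8, A=0 C=1 G=2 U=3) and a 4x4
pair-type matrix (-1 = unpairable) so the energy model stays outside.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e9


@njit(cache=True)
def nussinov_fill(enc, pmat, min_loop, max_span):
    """Maximum-pair DP table N[i, j] for subsequences i..j inclusive."""
    n = enc.shape[0]
    N = np.zeros((n + 1, n + 1), dtype=np.int32)  # row n = padding
    for l in range(min_loop + 1, min(n, max_span + 1)):
        for i in range(n - l):
            j = i + l
            best = N[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if pmat[enc[i], enc[k]] >= 0:
                    inner = N[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    rest = N[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + inner + rest
                    if cand > best:
                        best = cand
            N[i, j] = best
    return N


@njit(cache=True)
def zuker_fill(enc, pmat, stack, hp, it, ml_close, ml_branch, ml_unpaired,
               min_loop, max_interior, max_span):
    """Energy-model DP: V (pair-closed), WM/WM2 (multiloop parts).

    ``max_span`` limits j - i (used by the circular doubled-sequence
    reduction); pass n for an unconstrained linear fill.
    """
    n = enc.shape[0]
    # WM regions must contain >= 1 branch (so WM[i, i] stays INF and a
    # "multiloop" can never close over zero helices).
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    WM2 = np.full((n, n), INF)
    for l in range(1, n):
        if l > max_span:
            break
        for i in range(n - l):
            j = i + l
            pt = pmat[enc[i], enc[j]]
            if pt >= 0:
                best = hp[l - 1] if l - 1 <= n else INF
                # stacking / interior / bulge
                dmax = max_interior
                for d1 in range(0, dmax + 1):
                    p = i + 1 + d1
                    if p >= j:
                        break
                    for d2 in range(0, dmax - d1 + 1):
                        q = j - 1 - d2
                        if q <= p:
                            break
                        qt = pmat[enc[p], enc[q]]
                        if qt < 0:
                            continue
                        v = V[p, q]
                        if v >= INF:
                            continue
                        if d1 == 0 and d2 == 0:
                            cand = v + stack[pt, qt]
                        else:
                            cand = v + it[d1 + d2]
                        if cand < best:
                            best = cand
                # multiloop closed by (i, j)
                if j - i >= 2:
                    w2 = WM2[i + 1, j - 1]
                    if w2 < INF:
                        cand = w2 + ml_close + ml_branch
                        if cand < best:
                            best = cand
                V[i, j] = best
            # WM2: at least two branches
            best2 = INF
            for k in range(i, j):
                a = WM[i, k]
                b = WM[k + 1, j]
                if a + b < best2:
                    best2 = a + b
            WM2[i, j] = best2
            # WM: at least one branch
            bm = WM2[i, j]
            if V[i, j] + ml_branch < bm:
                bm = V[i, j] + ml_branch
            if WM[i + 1, j] + ml_unpaired < bm:
                bm = WM[i + 1, j] + ml_unpaired
            if WM[i, j - 1] + ml_unpaired < bm:
                bm = WM[i, j - 1] + ml_unpaired
            WM[i, j] = bm
    return V, WM, WM2


@njit(cache=True)
def exterior_fill(V, lo, hi):
    """Suffix exterior energies E[i] for the window [lo, hi).

    E[i] = best energy of positions i..hi-1 with free (unpenalised)
    exterior; returned array is indexed E[i - lo], length hi - lo + 1.
    """
    m = hi - lo
    E = np.zeros(m + 1)
    for i in range(hi - 1, lo - 1, -1):
        best = E[i - lo + 1]
        for j in range(i + 1, hi):
            v = V[i, j]
            if v < INF:
                cand = v + E[j + 1 - lo]
                if cand < best:
                    best = cand
        E[i - lo] = best
    return E


@njit(cache=True)
def best_circular_cut(V, n):
    """Best cut for a circular fold from the doubled-sequence V matrix.

    Returns (cut, energy) minimising the window exterior energy over all
    rotations; ties go to the smallest cut.
    """
    best_c = 0
    best_e = INF
    for c in range(n):
        E = exterior_fill(V, c, c + n)
        e = E[0]
        if e < best_e - 1e-12:
            best_e = e
            best_c = c
    return best_c, best_e


@njit(cache=True)
def best_circular_cut_pairs(N, n):
    """Best cut for circular max-pair folding from the doubled N table."""
    best_c = 0
    best_p = -1
    for c in range(n):
        p = N[c, c + n - 1]
        if p > best_p:
            best_p = p
            best_c = c
    return best_c, best_p
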