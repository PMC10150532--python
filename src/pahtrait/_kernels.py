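"""Numba-compiled inner loops (Viterbi scoring)."""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def viterbi_kernel(lo_m, lo_i, ltM, ltI, ltD, l_cont, l_exit, l_entry, seq):
    """Best-path local log2-odds score.

    States: match M_k emits, insert I_k (k < L-1) emits, delete D_k
    (k >= 1) silent.  Entry to any M_k costs l_entry, exit from M_k costs
    l_exit[k]; continuations out of M_k carry l_cont[k].  Residue index -1
    (unknown) is emitted by the background on every state (0 bits).
    """
    L = lo_m.shape[0]
    n = seq.shape[0]
    Mprev = np.full(L, NEG)
    Iprev = np.full(L, NEG)
    Dprev = np.full(L, NEG)
    Mcur = np.empty(L)
    Icur = np.full(L, NEG)
    Dcur = np.full(L, NEG)
    best = NEG
    for i in range(n):
        x = seq[i]
        for k in range(L):
            e = lo_m[k, x] if x >= 0 else 0.0
            v = l_entry
            if k > 0:
                a = Mprev[k - 1] + l_cont[k - 1] + ltM[k - 1, 0]
                if a > v:
                    v = a
                a = Iprev[k - 1] + ltI[k - 1, 0]
                if a > v:
                    v = a
                a = Dprev[k - 1] + ltD[k - 1, 0]
                if a > v:
                    v = a
            Mcur[k] = e + v
            s = Mcur[k] + l_exit[k]
            if s > best:
                best = s
        ei = lo_i[x] if x >= 0 else 0.0
        for k in range(L - 1):
            a = Mprev[k] + l_cont[k] + ltM[k, 1]
            b = Iprev[k] + ltI[k, 1]
            Icur[k] = ei + (a if a > b else b)
        for k in range(1, L):
            a = Mcur[k - 1] + l_cont[k - 1] + ltM[k - 1, 2]
            if k > 1:
                b = Dcur[k - 1] + ltD[k - 1, 1]
                if b > a:
                    a = b
            Dcur[k] = a
        Mprev, Mcur = Mcur, Mprev
        Iprev, Icur = Icur, Iprev
        Dprev, Dcur = Dcur, Dprev
    return best
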