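"""Independent brute-force oracles used by the tests.

These re-derive expected values by exhaustive enumeration and stay
independent of the implementation paths they check.
"""

from __future__ import annotations

import numpy as np

from pahtrait.profile_hmm import _log2_odds_tables, encode_sequence


def viterbi_enumerate(profile, residues: str) -> float:
    """Best local path score by explicit enumeration of every state path.

    Feasible for profile length <= 4 and sequence length <= 6; mirrors the
    model definition (entry/exit layer, free flanks) but shares no DP code
    with the scorer.
    """
    seq = encode_sequence(residues)
    lo_m, lo_i, ltM, ltI, ltD, l_cont, l_exit, l_entry = _log2_odds_tables(profile)
    L, n = profile.length, len(seq)
    best = [-np.inf]

    def em(k: int, x: int) -> float:
        return lo_m[k, x] if x >= 0 else 0.0

    def ei(x: int) -> float:
        return lo_i[x] if x >= 0 else 0.0

    def rec(state: str, k: int, i: int, sc: float) -> None:
        if state == "M":
            best[0] = max(best[0], sc + l_exit[k])
        if state == "M" and k < L - 1:
            if i < n:
                rec("M", k + 1, i + 1, sc + l_cont[k] + ltM[k, 0] + em(k + 1, seq[i]))
                rec("I", k, i + 1, sc + l_cont[k] + ltM[k, 1] + ei(seq[i]))
            rec("D", k + 1, i, sc + l_cont[k] + ltM[k, 2])
        elif state == "I":
            if i < n:
                rec("M", k + 1, i + 1, sc + ltI[k, 0] + em(k + 1, seq[i]))
                rec("I", k, i + 1, sc + ltI[k, 1] + ei(seq[i]))
        elif state == "D" and k < L - 1:
            if i < n:
                rec("M", k + 1, i + 1, sc + ltD[k, 0] + em(k + 1, seq[i]))
            rec("D", k + 1, i, sc + ltD[k, 1])

    for start in range(n):
        for ks in range(L):
            rec("M", ks, start + 1, l_entry + em(ks, seq[start]))
    return float(best[0])


def ga_scan(pos, neg) -> float:
    """Exhaustive threshold scan for the Youden-optimal GA.

    Candidates are all observed scores plus a value just above the
    maximum; the highest candidate attaining the maximal J wins.
    """
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    top = max(pos.max(), neg.max())
    cands = sorted(set(pos) | set(neg) | {np.nextafter(top, np.inf)})
    best_c, best_j = None, -np.inf
    for c in cands:
        j = (pos >= c).mean() + (neg < c).mean() - 1.0
        if j >= best_j:
            if j > best_j or (best_c is None or c > best_c):
                best_c, best_j = c, j
    return float(best_c)


def confusion_recount(y_true, y_pred) -> tuple[int, int, int, int]:
    """Count tp/tn/fp/fn by explicit iteration."""
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t and p:
            tp += 1
        elif t and not p:
            fn += 1
        elif not t and p:
            fp += 1
        else:
            tn += 1
    return tp, tn, fp, fn
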