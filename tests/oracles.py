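"""Independent brute-force oracles used by the test suite.

These deliberately avoid the dynamic-programming recurrences of the package:
the HMM oracle enumerates every legal state path, the alignment oracle
enumerates every chain of aligned residue pairs.  Both are exponential and
only usable on tiny inputs, which is the point.
"""

from __future__ import annotations

import numpy as np

from liposcan.alphabet import encode


def enumerate_hmm_paths(hmm, seq: str) -> tuple[float, float]:
    """(max, sum) of local path weights over every legal path, linear space.

    A path enters at any match state (weight 1/L), walks M/I/D states under
    the model's transition distributions, emits residues with emission/background
    odds, and may exit at any match state.  Flanking residues are free.
    """
    x = encode(seq)
    L = hmm.L
    t = hmm.transitions
    me = hmm.match_emissions / hmm.background
    ie = hmm.insert_emissions / hmm.background
    n = len(x)
    weights: list[float] = []

    def walk(state: str, k: int, i: int, w: float) -> None:
        # `state` at 0-based node k just acted; i = next unread seq index
        if state == "M":
            weights.append(w)  # exit here is allowed
        if k + 1 >= L:
            return
        if state == "M":
            if i < n:
                walk("M", k + 1, i + 1, w * t["mm"][k] * me[k + 1, x[i]])
                walk("I", k, i + 1, w * t["mi"][k] * ie[k + 1, x[i]])
            walk("D", k + 1, i, w * t["md"][k])
        elif state == "I":
            if i < n:
                walk("M", k + 1, i + 1, w * t["im"][k] * me[k + 1, x[i]])
                walk("I", k, i + 1, w * t["ii"][k] * ie[k + 1, x[i]])
        elif state == "D":
            if i < n:
                walk("M", k + 1, i + 1, w * t["dm"][k] * me[k + 1, x[i]])
            walk("D", k + 1, i, w * t["dd"][k])

    for i0 in range(n):
        for b in range(L):
            walk("M", b, i0 + 1, (1.0 / L) * me[b, x[i0]])
    return max(weights), sum(weights)


def brute_force_local_score(a: str, b: str, scheme) -> float:
    """Optimal local alignment score by enumerating all aligned-pair chains.

    An alignment is a strictly monotone chain of residue pairs; between
    consecutive pairs, dx unaligned query residues cost gap_open + dx *
    gap_extend (likewise dy in the target).  Only usable for |a|, |b| <= ~6.
    """
    mat = scheme.matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    n, m = len(a), len(b)
    best = 0.0

    def gap_cost(d: int) -> float:
        return go + d * ge if d > 0 else 0.0

    def extend(i: int, j: int, acc: float) -> None:
        nonlocal best
        best = max(best, acc)
        for ii in range(i + 1, n):
            for jj in range(j + 1, m):
                s = acc - gap_cost(ii - i - 1) - gap_cost(jj - j - 1) + mat[a[ii], b[jj]]
                extend(ii, jj, s)

    for i in range(n):
        for j in range(m):
            extend(i, j, float(mat[a[i], b[j]]))
    return best
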