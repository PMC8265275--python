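"""Independent reference implementations used as test oracles.

Each oracle recomputes a quantity by a different route than the library
(set arithmetic, naive quadratic formulas, memoized recursive enumeration)
so that agreement is informative.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from cernax.mirna_target import (
    GAP_EXTEND,
    GAP_OPEN,
    GU_SCORE,
    MISMATCH_SCORE,
    SEED_POSITIONS,
    SEED_WEIGHT,
    WC_SCORE,
    MAX_BULGE,
    MAX_ILOOP,
    _BULGE,
    _ILOOP,
    _pair_kind,
    _stack_energy,
)


def relation_oracle(lnc, mrna, up_window, down_window):
    """Interval relation by explicit position-set arithmetic."""
    if lnc.chrom != mrna.chrom:
        return "none"
    lset = set(range(lnc.start, lnc.end + 1))
    mset = set(range(mrna.start, mrna.end + 1))
    if lset & mset:
        return "overlap" if lnc.strand == mrna.strand else "anti-overlap"
    gap = min(abs(a - b) for a in (lnc.start, lnc.end) for b in (mrna.start, mrna.end))
    lnc_left = max(lset) < min(mset)
    upstream = lnc_left if mrna.strand == "+" else not lnc_left
    if upstream:
        return "upstream" if gap <= up_window else "none"
    return "downstream" if gap <= down_window else "none"


def bh_oracle(pvals):
    """Naive O(m^2) Benjamini-Hochberg: q_i = min over p_j >= p_i of m*p_j/rank_j."""
    p = list(pvals)
    m = len(p)
    ranks = [sum(1 for x in p if x <= pj) for pj in p]
    out = []
    for pi in p:
        candidates = [m * pj / rj for pj, rj in zip(p, ranks) if pj >= pi]
        out.append(min(1.0, min(candidates)))
    return np.array(out)


def longest_orf_oracle(seq):
    """Exhaustive scan over every ATG/stop codon position pair."""
    s = seq.upper().replace("U", "T")
    best = (0, 0)
    for i in range(len(s) - 2):
        if s[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(s) - 2, 3):
            if s[j : j + 3] in ("TAA", "TAG", "TGA"):
                length = j + 3 - i
                if length > best[1]:
                    best = (i + 1, length)
                break
    return best


def align_score_oracle(mirna: str, window: str) -> float:
    """Local alignment score by memoized recursion over alignment paths."""
    q = mirna.upper().replace("T", "U")
    t = window.upper().replace("T", "U")[::-1]
    n, m = len(q), len(t)

    def pair_score(i: int, j: int) -> float:
        kind = _pair_kind(q[i], t[j])
        base = WC_SCORE if kind == "WC" else GU_SCORE if kind == "GU" else MISMATCH_SCORE
        return base * (SEED_WEIGHT if (i + 1) in SEED_POSITIONS else 1.0)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        # best score of an alignment continuing from (i, j); stopping is free
        options = [0.0]
        if i < n and j < m:
            options.append(pair_score(i, j) + rec(i + 1, j + 1, "M"))
        if i < n:
            options.append((GAP_EXTEND if state == "X" else GAP_OPEN) + rec(i + 1, j, "X"))
        if j < m:
            options.append((GAP_EXTEND if state == "Y" else GAP_OPEN) + rec(i, j + 1, "Y"))
        return max(options)

    best = 0.0
    for i in range(n):
        for j in range(m):
            if _pair_kind(q[i], t[j]) is not None:
                best = max(best, pair_score(i, j) + rec(i + 1, j + 1, "M"))
    return best


def duplex_mfe_oracle(s1: str, s2: str) -> float:
    """Duplex MFE by memoized forward enumeration of pair chains."""
    x = s1.upper().replace("T", "U")
    y = s2.upper().replace("T", "U")
    n, m = len(x), len(y)

    def step(a: int, b: int, p1, p2):
        if a == 0 and b == 0:
            return _stack_energy(p1, p2)
        if a == 0 or b == 0:
            return _BULGE.get(a + b) if a + b <= MAX_BULGE else None
        return _ILOOP.get(a + b) if a + b <= MAX_ILOOP else None

    @lru_cache(maxsize=None)
    def extend(i: int, j: int) -> float:
        # best energy of continuing a duplex whose last pair is (i, j)
        best = 0.0
        for i2 in range(i + 1, min(n, i + MAX_ILOOP + 2)):
            for j2 in range(max(-1, j - MAX_ILOOP - 2) + 1, j):
                if _pair_kind(x[i2], y[j2]) is None:
                    continue
                cost = step(i2 - i - 1, j - j2 - 1, (x[i], y[j]), (x[i2], y[j2]))
                if cost is None:
                    continue
                best = min(best, cost + extend(i2, j2))
        return best

    best = 0.0
    for i in range(n):
        for j in range(m):
            if _pair_kind(x[i], y[j]) is not None:
                best = min(best, extend(i, j))
    return best


def correlation_oracle(x, y):
    """Two-pass Pearson and rank-transform Spearman."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    def pearson(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))
    def avg_rank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    return pearson(x, y), pearson(avg_rank(x), avg_rank(y))
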