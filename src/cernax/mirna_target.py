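"""miRNA binding-site discovery: seed scanning, position-weighted
complementarity alignment, intermolecular duplex free energy, and the
score/energy gates that admit a site.

Two scoring routes mirror the two tool families used for animal miRNA
target prediction.  The alignment route (miRanda-style) finds the best
antiparallel local alignment of the miRNA against a target window under
Watson-Crick +5, G:U +2, mismatch -3, gap open -9 / extend -4, with all
contributions at miRNA seed positions 2-8 weighted fourfold.  The energy
route (RNAhybrid-style) computes the minimum free energy over all
intermolecular secondary structures (no intramolecular pairs, no
pseudoknots) using a hard-coded nearest-neighbor stacking table with
loop/bulge penalties.  A site passes when the alignment score, the
energy of the aligned duplex, and the unconstrained hybrid energy all
clear their thresholds (external tool scales: score >= 300,
MFE <= -45 kcal/mol, MFE <= -30 kcal/mol; the score gate is rescaled
onto the built-in scale, see ``INTERNAL_SCORE_GATE``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "MirnaSite",
    "MirnaThresholds",
    "PairSign",
    "align_score",
    "duplex_mfe",
    "duplex_energy_of_pairs",
    "seed_match_positions",
    "scan_targets",
    "pair_sign",
    "INTERNAL_SCORE_GATE",
]

# --- scoring constants (alignment route) ------------------------------------

WC_SCORE = 5.0
GU_SCORE = 2.0
MISMATCH_SCORE = -3.0
GAP_OPEN = -9.0
GAP_EXTEND = -4.0
SEED_WEIGHT = 4.0
SEED_POSITIONS = range(2, 9)  # miRNA positions 2-8, 1-based

#: external-tool-scale gates
EXTERNAL_SCORE_GATE = 300.0
ALIGN_MFE_GATE = -45.0
HYBRID_MFE_GATE = -30.0

#: built-in score of a perfectly complemented 22-mer is 7*5*4 + 15*5 = 215,
#: against ~460 for the corresponding external perfect score; the external
#: gate of 300 maps onto the built-in scale by that ratio.
PERFECT_22MER_SCORE = 215.0
EXTERNAL_PERFECT_SCORE = 460.0
INTERNAL_SCORE_GATE = EXTERNAL_SCORE_GATE * PERFECT_22MER_SCORE / EXTERNAL_PERFECT_SCORE

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def _rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    for i, ch in enumerate(s):
        if ch not in "ACGU":
            raise ValueError(f"invalid nucleotide {ch!r} at position {i + 1}")
    return s


def _pair_kind(a: str, b: str) -> str | None:
    if (a, b) in _WC:
        return "WC"
    if (a, b) in _GU:
        return "GU"
    return None


# --- duplex free energy (hybridization route) -------------------------------

# Nearest-neighbor stack free energies in kcal/mol at 37 C, collapsed to the
# unordered pair-class level (GC-type, AU-type, G:U wobble) of the two
# stacked pairs; magnitudes follow published Turner-style scales.
_PAIR_CLASS = {("G", "C"): "GC", ("C", "G"): "GC",
               ("A", "U"): "AU", ("U", "A"): "AU",
               ("G", "U"): "GU", ("U", "G"): "GU"}
_STACK = {
    frozenset(["GC"]): -3.3,
    frozenset(["GC", "AU"]): -2.4,
    frozenset(["GC", "GU"]): -2.1,
    frozenset(["AU"]): -1.1,
    frozenset(["AU", "GU"]): -1.4,
    frozenset(["GU"]): -0.5,
}
#: bulge penalties by bulge length (1-3 nt) and internal-loop penalties by
#: total loop length (2-4 nt)
_BULGE = {1: 3.8, 2: 2.8, 3: 3.2}
_ILOOP = {2: 1.5, 3: 2.2, 4: 2.7}
MAX_BULGE = 3
MAX_ILOOP = 4


def _stack_energy(p1: tuple[str, str], p2: tuple[str, str]) -> float:
    return _STACK[frozenset([_PAIR_CLASS[p1], _PAIR_CLASS[p2]])]


def _step_cost(a: int, b: int, p1: tuple[str, str], p2: tuple[str, str]) -> float | None:
    """Cost of extending a duplex from one pair to the next.

    ``a``/``b`` are the numbers of unpaired nucleotides skipped on each
    strand; stacked pairs (0/0) contribute the stack energy, single-strand
    skips a bulge penalty, two-sided skips an internal-loop penalty.
    Returns None when the step exceeds the loop-size limits.
    """
    if a == 0 and b == 0:
        return _stack_energy(p1, p2)
    if a == 0 or b == 0:
        t = a + b
        return _BULGE[t] if t <= MAX_BULGE else None
    t = a + b
    return _ILOOP[t] if t <= MAX_ILOOP else None


def duplex_mfe(s1: str, s2: str) -> float:
    """Minimum free energy of an intermolecular duplex of two RNAs.

    Both sequences are given 5'->3'; the duplex is antiparallel, so paired
    positions advance along ``s1`` while receding along ``s2``.  Dynamic
    programming over "last pair" states; a structure with no stabilizing
    pairs scores 0 (the function never returns a positive value).
    """
    x = _rna(s1)
    y = _rna(s2)
    if not x or not y:
        raise ValueError("empty sequence")
    n, m = len(x), len(y)
    NEG = float("inf")
    # E[i][j]: best energy of a duplex whose 3'-most pair (along s1) is (i, j)
    E = [[NEG] * m for _ in range(n)]
    best = 0.0
    for i in range(n):
        for j in range(m - 1, -1, -1):
            p2 = (x[i], y[j])
            if _pair_kind(*p2) is None:
                continue
            e = 0.0  # duplex may begin at this pair
            lo_i = max(0, i - (MAX_ILOOP + 1))
            for i0 in range(lo_i, i):
                a = i - i0 - 1
                row = E[i0]
                for j0 in range(j + 1, min(m, j + MAX_ILOOP + 2)):
                    if row[j0] == NEG:
                        continue
                    b = j0 - j - 1
                    cost = _step_cost(a, b, (x[i0], y[j0]), p2)
                    if cost is None:
                        continue
                    e = min(e, row[j0] + cost)
            E[i][j] = e
            best = min(best, e)
    return best


def duplex_energy_of_pairs(s1: str, s2: str, chain: list[tuple[int, int]]) -> float:
    """Energy of one explicit duplex given as 0-based pair indices.

    ``chain`` must advance along ``s1`` and recede along ``s2``; steps
    violating the loop-size limits contribute no stabilizing energy and
    split the duplex (each maximal valid segment is summed, the total is
    capped at 0).
    """
    x = _rna(s1)
    y = _rna(s2)
    total = 0.0
    segment = 0.0
    for k, (i, j) in enumerate(chain):
        if _pair_kind(x[i], y[j]) is None:
            raise ValueError(f"chain pair ({i}, {j}) is not complementary")
        if k == 0:
            continue
        i0, j0 = chain[k - 1]
        if i <= i0 or j >= j0:
            raise ValueError("chain must advance on s1 and recede on s2")
        cost = _step_cost(i - i0 - 1, j0 - j - 1, (x[i0], y[j0]), (x[i], y[j]))
        if cost is None:
            total += min(segment, 0.0)
            segment = 0.0
        else:
            segment += cost
    total += min(segment, 0.0)
    return min(total, 0.0)


# --- position-weighted complementarity alignment ----------------------------

def _base_pair_score(a: str, b: str) -> float:
    kind = _pair_kind(a, b)
    if kind == "WC":
        return WC_SCORE
    if kind == "GU":
        return GU_SCORE
    return MISMATCH_SCORE


def align_score(mirna: str, window: str) -> tuple[float, dict[int, int]]:
    """Best antiparallel local complementarity alignment score.

    The miRNA (5'->3', 18-26 nt) is aligned against the window read
    3'->5', so alignment columns are candidate base pairs.  Pair and
    mismatch contributions at miRNA positions 2-8 are weighted fourfold;
    gaps use affine penalties and the local-alignment floor is 0.
    Returns the score and a map of 1-based miRNA position -> 1-based
    window position for the paired columns of the best alignment.
    """
    q = _rna(mirna)
    if not (18 <= len(q) <= 26):
        raise ValueError(f"miRNA length {len(q)} outside 18-26 nt")
    w = _rna(window)
    if len(w) < len(q):
        raise ValueError("window shorter than miRNA")
    t = w[::-1]  # align against the window read 3'->5'
    n, m = len(q), len(t)
    NEG = -1e18
    # affine-gap Smith-Waterman; M = column is a (mis)pair, X/Y = gap states
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, best_ij = 0.0, None
    for i in range(1, n + 1):
        weight = SEED_WEIGHT if i in SEED_POSITIONS else 1.0
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] + GAP_OPEN, X[i - 1][j] + GAP_EXTEND)
            Y[i][j] = max(M[i][j - 1] + GAP_OPEN, Y[i][j - 1] + GAP_EXTEND)
            s = weight * _base_pair_score(q[i - 1], t[j - 1])
            M[i][j] = max(
                0.0,
                M[i - 1][j - 1] + s,
                X[i - 1][j - 1] + s,
                Y[i - 1][j - 1] + s,
            )
            if M[i][j] > best:
                best, best_ij = M[i][j], (i, j)
    pairs: dict[int, int] = {}
    if best_ij is not None:
        i, j = best_ij
        state = "M"
        while i > 0 and j > 0:
            if state == "M":
                if M[i][j] == 0.0:
                    break
                weight = SEED_WEIGHT if i in SEED_POSITIONS else 1.0
                s = weight * _base_pair_score(q[i - 1], t[j - 1])
                if _pair_kind(q[i - 1], t[j - 1]) is not None:
                    pairs[i] = m - j + 1  # back to 5'->3' window coordinates
                if M[i - 1][j - 1] + s == M[i][j]:
                    state = "M"
                elif X[i - 1][j - 1] + s == M[i][j]:
                    state = "X"
                else:
                    state = "Y"
                i, j = i - 1, j - 1
            elif state == "X":
                state = "M" if X[i][j] == M[i - 1][j] + GAP_OPEN else "X"
                i -= 1
            else:
                state = "M" if Y[i][j] == M[i][j - 1] + GAP_OPEN else "Y"
                j -= 1
    return best, pairs


# --- seed scanning and site gates -------------------------------------------

def seed_match_positions(mirna: str, target: str, max_gu: int = 1) -> list[int]:
    """0-based target positions whose 7-mer pairs miRNA positions 2-8.

    A seed match requires every one of miRNA positions 2-8 paired
    (antiparallel) with at most ``max_gu`` G:U wobbles and no mismatch.
    """
    q = _rna(mirna)
    t = _rna(target)
    seed = q[1:8]  # positions 2-8
    hits = []
    for pos in range(len(t) - 6):
        word = t[pos : pos + 7]
        gu = 0
        ok = True
        for k in range(7):
            kind = _pair_kind(seed[k], word[6 - k])
            if kind is None:
                ok = False
                break
            if kind == "GU":
                gu += 1
                if gu > max_gu:
                    ok = False
                    break
        if ok:
            hits.append(pos)
    return hits


@dataclass(frozen=True)
class MirnaThresholds:
    """Site gates; ``score_gate`` defaults to the built-in calibrated scale."""

    score_gate: float = INTERNAL_SCORE_GATE
    align_mfe_gate: float = ALIGN_MFE_GATE
    hybrid_mfe_gate: float = HYBRID_MFE_GATE
    max_seed_gu: int = 1


@dataclass
class MirnaSite:
    """A scored candidate binding site on a target transcript."""

    mirna_id: str
    target_id: str
    target_start: int  # 1-based, inclusive
    target_end: int
    align_score: float
    align_mfe: float
    hybrid_mfe: float
    seed_class: str  # 7mer-WC | 7mer-1GU
    passes: bool


@dataclass(frozen=True)
class PairSign:
    sign: str  # positive | negative


def _seed_class(mirna: str, target: str, seed_pos: int) -> str:
    q = _rna(mirna)[1:8]
    word = _rna(target)[seed_pos : seed_pos + 7]
    gu = sum(1 for k in range(7) if _pair_kind(q[k], word[6 - k]) == "GU")
    return "7mer-1GU" if gu else "7mer-WC"


def scan_targets(
    mirna: str,
    target_seq: str,
    thresholds: MirnaThresholds | None = None,
    mirna_id: str = "mirna",
    target_id: str = "target",
    window: int = 30,
    stride: int = 5,
) -> list[MirnaSite]:
    """Scan a target transcript for candidate miRNA binding sites.

    Seed matches (positions 2-8, <= 1 G:U, no mismatch) anchor candidate
    windows on a ``stride`` grid; each candidate window is scored by the
    alignment and hybridization routes and gated.  Overlapping passing
    sites are merged, keeping the best-scoring representative.
    """
    if thresholds is None:
        thresholds = MirnaThresholds()
    t = _rna(target_seq)
    if len(t) < window:
        raise ValueError(f"target shorter than the {window}-nt scan window")
    hits = seed_match_positions(mirna, t, thresholds.max_seed_gu)
    if not hits:
        return []
    starts = list(range(0, len(t) - window + 1, stride))
    if starts[-1] != len(t) - window:
        starts.append(len(t) - window)
    sites: list[MirnaSite] = []
    for h in hits:
        covering = [s for s in starts if s <= h and h + 7 <= s + window]
        if not covering:
            continue
        # pick the covering window best centred on the expected full site:
        # miRNA 3'-supplementary pairing extends 5' of the seed on the target
        ws = min(covering, key=lambda s: abs((h - 4) - (s + window // 2)))
        win = t[ws : ws + window]
        score, pairmap = align_score(mirna, win)
        if pairmap:
            tpos = sorted(pairmap.values())
            start, end = ws + tpos[0], ws + tpos[-1]
            # energy of the aligned duplex: miRNA advances 5'->3' while the
            # window position recedes (antiparallel pairing)
            chain = sorted(((mp - 1, wp - 1) for mp, wp in pairmap.items()))
            amfe = duplex_energy_of_pairs(mirna, win, chain)
        else:
            start, end = ws + h + 1, ws + h + 7
            amfe = 0.0
        hmfe = duplex_mfe(mirna, win)
        passes = (
            score >= thresholds.score_gate
            and amfe <= thresholds.align_mfe_gate
            and hmfe <= thresholds.hybrid_mfe_gate
        )
        sites.append(
            MirnaSite(
                mirna_id=mirna_id,
                target_id=target_id,
                target_start=start,
                target_end=end,
                align_score=score,
                align_mfe=amfe,
                hybrid_mfe=hmfe,
                seed_class=_seed_class(mirna, t, h),
                passes=passes,
            )
        )
    return _merge_overlapping(sites)


def _merge_overlapping(sites: list[MirnaSite]) -> list[MirnaSite]:
    """Merge overlapping passing sites, keeping the best score per cluster."""
    passing = sorted(
        (s for s in sites if s.passes), key=lambda s: (s.target_start, s.target_end)
    )
    failing = [s for s in sites if not s.passes]
    merged: list[MirnaSite] = []
    for s in passing:
        if merged and s.target_start <= merged[-1].target_end:
            if s.align_score > merged[-1].align_score:
                merged[-1] = s
        else:
            merged.append(s)
    out = merged + failing
    out.sort(key=lambda s: (s.target_start, s.target_end))
    return out


def pair_sign(dir_mirna: str, dir_target: str) -> PairSign:
    """Sign of a DE miRNA / DE target pair: negative iff directions differ."""
    for d in (dir_mirna, dir_target):
        if d not in ("Up", "Down"):
            raise ValueError(f"direction must be Up or Down, got {d!r}")
    return PairSign("negative" if dir_mirna != dir_target else "positive")
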