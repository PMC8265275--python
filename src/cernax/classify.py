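"""Transcript coding-ability classification and small-RNA annotation priority.

Novel transcripts are labelled mRNA or lncRNA by an ensemble vote over four
coding-potential assessments (CPC-like score, txCdsPredict-like score,
CNC-like score, Pfam hit): a transcript is called when at least three of
the four methods agree.  The thresholds are CPC < 0, txCdsPredict < 500,
CNC < 0 and absence from Pfam, each counting as one noncoding vote;
comparisons are strict, so a score exactly at the threshold votes coding.

When external tool outputs are unavailable the module provides a built-in
scorer on the same scales: the txCdsPredict-like score is the longest ORF
length in nucleotides, the CPC-like score is ORF coverage minus 0.3, and
the CNC-like score is the Fickett TESTCODE statistic minus 0.95 (0.95
being TESTCODE's classical coding threshold), so the published thresholds
keep their meaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CodingScores",
    "BiotypeCall",
    "vote_biotype",
    "longest_orf",
    "fickett_score",
    "builtin_coding_scores",
    "annotate_small_rna",
]

_STOPS = {"TAA", "TAG", "TGA"}

SMALL_RNA_PRIORITY = ("miRBase", "piRNAbank", "snoRNA", "Rfam")


@dataclass(frozen=True)
class CodingScores:
    """The four coding-potential assessments for one transcript."""

    cpc: float
    txcds: float
    cnc: float
    pfam_hit: bool

    def __post_init__(self) -> None:
        for name in ("cpc", "txcds", "cnc"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite {name} score")


@dataclass(frozen=True)
class BiotypeCall:
    biotype: str  # mRNA | lncRNA | ambiguous
    noncoding_votes: int
    coding_votes: int


def vote_biotype(scores: CodingScores) -> BiotypeCall:
    """Apply the 3-of-4 ensemble vote.

    Noncoding votes: cpc < 0, txcds < 500, cnc < 0, no Pfam hit.  A 2-2
    split is labelled ``ambiguous`` and excluded from both downstream sets.
    """
    noncoding = sum(
        [scores.cpc < 0, scores.txcds < 500, scores.cnc < 0, not scores.pfam_hit]
    )
    coding = 4 - noncoding
    if noncoding >= 3:
        biotype = "lncRNA"
    elif coding >= 3:
        biotype = "mRNA"
    else:
        biotype = "ambiguous"
    return BiotypeCall(biotype=biotype, noncoding_votes=noncoding, coding_votes=coding)


def longest_orf(seq: str) -> tuple[int, int]:
    """Longest ATG…stop open reading frame on the forward strand.

    Scans all three frames; returns (1-based start, length in nt including
    the stop codon), or (0, 0) when no complete ORF exists.
    """
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in "ACGT":
            raise ValueError(f"invalid character {ch!r} at position {i + 1}")
    best = (0, 0)
    n = len(s)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = s[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                length = i + 3 - start
                if length > best[1]:
                    best = (start + 1, length)
                start = None
    return best


# Fickett TESTCODE lookup tables (position-asymmetry and composition
# parameters with their classical probability bins and weights).
_FICKETT_POS_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_FICKETT_POS_BINS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1]
_FICKETT_POS_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_FICKETT_CONT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_FICKETT_CONT_BINS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17]
_FICKETT_CONT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def _bin_lookup(value: float, bins: list[float], probs: list[float]) -> float:
    for i, cut in enumerate(bins):
        if value >= cut:
            return probs[i]
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence.

    Combines, for each base, a position parameter (asymmetry of the base
    across the three codon positions, max/(min+1)) and a content parameter
    (base fraction), each mapped through the classical probability tables
    and weighted.  Values above ~0.95 indicate coding sequence.
    """
    s = seq.upper().replace("U", "T")
    score = 0.0
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    for base in "ACGT":
        counts = [s[off::3].count(base) for off in range(3)]
        pos_value = max(counts) / (min(counts) + 1.0)
        score += (
            _bin_lookup(pos_value, _FICKETT_POS_BINS, _FICKETT_POS_PROB[base])
            * _FICKETT_POS_WEIGHT[base]
        )
        content = s.count(base) / n
        score += (
            _bin_lookup(content, _FICKETT_CONT_BINS, _FICKETT_CONT_PROB[base])
            * _FICKETT_CONT_WEIGHT[base]
        )
    return score


def builtin_coding_scores(seq: str) -> CodingScores:
    """Built-in stand-in scorer on the external tools' threshold scales.

    Requires length >= 200 nt (the lncRNA definition floor).  When an
    external score table is supplied to the pipeline it takes precedence
    over this scorer.
    """
    if len(seq) < 200:
        raise ValueError(f"sequence shorter than 200 nt ({len(seq)} nt)")
    _start, orf_len = longest_orf(seq)
    coverage = orf_len / len(seq)
    return CodingScores(
        cpc=coverage - 0.3,
        txcds=float(orf_len),
        cnc=fickett_score(seq) - 0.95,
        pfam_hit=False,
    )


def annotate_small_rna(hits: set[str] | frozenset[str]) -> str:
    """Resolve a small-RNA read's category by database priority.

    Priority order: miRBase > piRNAbank > snoRNA > Rfam; an empty hit set
    is ``unannotated``.
    """
    unknown = set(hits) - set(SMALL_RNA_PRIORITY)
    if unknown:
        raise ValueError(f"unknown database label(s): {sorted(unknown)}")
    for db in SMALL_RNA_PRIORITY:
        if db in hits:
            return db
    return "unannotated"
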