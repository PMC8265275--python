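"""lncRNA target assignment: genomic window rule, overlap classes,
co-expression gate, and the windowed duplex-energy trans rule.

A lncRNA is a candidate cis regulator of an mRNA when it lies within
10 kb upstream or 20 kb downstream of it (boundaries inclusive, distances
between nearest transcript boundaries, upstream/downstream taken relative
to the mRNA's strand); intersecting spans are classed overlap or
anti-overlap by strand equality.  A positional pair becomes a target pair
only when both Pearson and Spearman expression correlations reach 0.6.
A lncRNA outside the window is a trans candidate when its best windowed
duplex energy against the mRNA falls below -30 kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from cernax.core_io import CountMatrix, TranscriptRecord
from cernax.diffexpr import DEResult
from cernax.mirna_target import duplex_mfe

__all__ = [
    "CisPair",
    "classify_relation",
    "expression_correlation",
    "trans_candidate",
    "build_cis_pairs",
]

UP_WINDOW = 10_000
DOWN_WINDOW = 20_000
CORR_THRESHOLD = 0.6
TRANS_MFE_THRESHOLD = -30.0


@dataclass
class CisPair:
    """A positional lncRNA–mRNA pair with its co-expression evidence."""

    lnc_id: str
    mrna_id: str
    relation: str  # upstream | downstream | overlap | anti-overlap
    distance: float
    pearson: float
    spearman: float
    passes_correlation: bool
    mrna_is_de: bool = False


def classify_relation(
    lnc: TranscriptRecord,
    mrna: TranscriptRecord,
    up_window: int = UP_WINDOW,
    down_window: int = DOWN_WINDOW,
) -> tuple[str, float]:
    """Positional relation of a lncRNA to an mRNA, and their gap in nt.

    Different chromosomes give ("none", inf).  Intersecting spans give
    ("overlap", 0) on the same strand and ("anti-overlap", 0) otherwise.
    Disjoint spans return the nearest-boundary gap; the relation is
    "upstream" when the lncRNA lies 5' of the mRNA with respect to the
    mRNA's strand and the gap is within ``up_window`` (inclusive),
    "downstream" within ``down_window``, and "none" (with the gap still
    reported) beyond the windows.
    """
    for rec in (lnc, mrna):
        if rec.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {rec.strand!r}")
    if lnc.chrom != mrna.chrom:
        return "none", math.inf
    if lnc.start <= mrna.end and mrna.start <= lnc.end:
        return ("overlap", 0.0) if lnc.strand == mrna.strand else ("anti-overlap", 0.0)
    if lnc.end < mrna.start:
        gap = float(mrna.start - lnc.end)
        lnc_left = True
    else:
        gap = float(lnc.start - mrna.end)
        lnc_left = False
    upstream_side = lnc_left if mrna.strand == "+" else not lnc_left
    if upstream_side:
        return ("upstream", gap) if gap <= up_window else ("none", gap)
    return ("downstream", gap) if gap <= down_window else ("none", gap)


def expression_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson and Spearman correlations of two per-sample expression vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman


def trans_candidate(
    lnc_seq: str,
    mrna_seq: str,
    window: int = 40,
    step: int = 20,
    mfe_threshold: float = TRANS_MFE_THRESHOLD,
) -> tuple[float, bool]:
    """Minimum windowed duplex energy between two transcripts.

    Slides a ``window``-nt window at the given ``step`` over both
    sequences (the final partial-offset window is anchored at the
    sequence end) and evaluates the intermolecular duplex MFE of every
    window pair; a trans interaction is called when the minimum falls
    below ``mfe_threshold`` kcal/mol.
    """
    if len(lnc_seq) < window or len(mrna_seq) < window:
        raise ValueError("sequence shorter than the scan window")

    def _starts(n: int) -> list[int]:
        starts = list(range(0, n - window + 1, step))
        if starts[-1] != n - window:
            starts.append(n - window)
        return starts

    best = 0.0
    for i in _starts(len(lnc_seq)):
        wi = lnc_seq[i : i + window]
        for j in _starts(len(mrna_seq)):
            best = min(best, duplex_mfe(wi, mrna_seq[j : j + window]))
    return best, best < mfe_threshold


def build_cis_pairs(
    annotation: list[TranscriptRecord],
    expression: CountMatrix,
    de_lnc: list[DEResult],
    de_mrna: list[DEResult],
    up_window: int = UP_WINDOW,
    down_window: int = DOWN_WINDOW,
    corr_threshold: float = CORR_THRESHOLD,
) -> list[CisPair]:
    """All correlation-passing positional pairs of DE lncRNAs with mRNAs.

    For every significantly DE lncRNA and every annotated mRNA on the same
    chromosome with a relation other than "none", expression correlations
    are computed across all samples (both groups pooled); pairs passing
    both correlation gates are emitted, flagged when the mRNA itself is DE.
    """
    records = {r.transcript_id: r for r in annotation}
    fid_index = {f: i for i, f in enumerate(expression.feature_ids)}
    sig_lnc = [r for r in de_lnc if r.significant]
    de_mrna_ids = {r.feature_id for r in de_mrna if r.significant}
    mrnas_by_chrom: dict[str, list[TranscriptRecord]] = {}
    for rec in annotation:
        if rec.biotype == "mRNA":
            mrnas_by_chrom.setdefault(rec.chrom, []).append(rec)

    pairs: list[CisPair] = []
    for lres in sig_lnc:
        lnc = records.get(lres.feature_id)
        if lnc is None or lres.feature_id not in fid_index:
            raise ValueError(f"lncRNA {lres.feature_id!r} missing from annotation or expression")
        x = expression.values[fid_index[lnc.transcript_id]]
        for mrna in mrnas_by_chrom.get(lnc.chrom, []):
            relation, distance = classify_relation(lnc, mrna, up_window, down_window)
            if relation == "none":
                continue
            if mrna.transcript_id not in fid_index:
                raise ValueError(f"mRNA {mrna.transcript_id!r} missing from expression")
            y = expression.values[fid_index[mrna.transcript_id]]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # no expression variation: gate cannot be evaluated
            pearson, spearman = expression_correlation(x, y)
            passes = pearson >= corr_threshold and spearman >= corr_threshold
            if passes:
                pairs.append(
                    CisPair(
                        lnc_id=lnc.transcript_id,
                        mrna_id=mrna.transcript_id,
                        relation=relation,
                        distance=distance,
                        pearson=pearson,
                        spearman=spearman,
                        passes_correlation=True,
                        mrna_is_de=mrna.transcript_id in de_mrna_ids,
                    )
                )
    return pairs
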