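"""Count normalization, fold change, significance testing and the DE gate.

The differential-expression statistic is a pooled binomial proportion
z-test: within each group the replicate counts of a feature are summed,
and the H-group share of the pooled total is tested against the share
expected from the two group library sizes.  This is the closest defined
statistic to the random-sampling model used by two-library count DE tools.
Fold changes are computed on group means of normalized per-sample values,
with a pseudo-expression floor applied only to the ratio (never to the
test).  Significance uses the inclusive gates |FC| >= 2 and Q <= 0.001,
with Q from Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from cernax.core_io import CountMatrix, GroupDesign

__all__ = [
    "DEResult",
    "ScaleConstant",
    "normalize",
    "log2_fold_change",
    "fit_scale_from_reference",
    "de_test",
    "bh_adjust",
    "call_de",
    "fpkm_bins",
    "de_table",
    "PSEUDO_EXPRESSION",
]

#: pseudo-expression (normalized units) added to zero group means before the
#: log2 ratio only; testing always sees the raw counts.
PSEUDO_EXPRESSION = 0.1


@dataclass
class DEResult:
    """Per-feature differential-expression summary."""

    feature_id: str
    mean_L: float
    mean_H: float
    log2fc: float
    p: float
    q: float = float("nan")
    direction: str = "none"  # Up | Down | none
    significant: bool = False


@dataclass(frozen=True)
class ScaleConstant:
    """Multiplier applied to the raw H/L expression ratio before log2.

    Absorbs undocumented between-library scaling when reproducing published
    fold changes from printed group expression values.
    """

    c: float

    def __post_init__(self) -> None:
        if not (self.c > 0):
            raise ValueError("scale constant must be positive")


def normalize(
    counts: CountMatrix, design: GroupDesign
) -> tuple[CountMatrix, np.ndarray]:
    """Scale each sample to counts-per-million of its column total."""
    if counts.unit != "count":
        raise ValueError("normalize expects raw counts")
    totals = counts.values.sum(axis=0)
    if np.any(totals == 0):
        bad = [s for s, t in zip(counts.sample_ids, totals) if t == 0]
        raise ValueError(f"zero-total sample column(s): {bad}")
    factors = 1e6 / totals
    normed = CountMatrix(
        feature_ids=list(counts.feature_ids),
        sample_ids=list(counts.sample_ids),
        values=counts.values * factors,
        unit="count",
    )
    return normed, factors


def log2_fold_change(mean_L: float, mean_H: float, scale: ScaleConstant | None = None) -> float:
    """log2 of the (optionally rescaled) H/L expression ratio."""
    if mean_L <= 0 or mean_H <= 0:
        raise ValueError("group means must be positive (apply a pseudocount upstream)")
    c = scale.c if scale is not None else 1.0
    return math.log2(c * mean_H / mean_L)


def fit_scale_from_reference(
    rows: list[tuple[float, float, float]]
) -> ScaleConstant:
    """Fit the between-library scale constant from reference rows.

    Each row is (mean_L, mean_H, published_log2fc); the per-row implied
    constant is 2**log2fc / (H/L) and the median over rows is returned.
    """
    if not rows:
        raise ValueError("need at least one reference row")
    implied = []
    for mean_L, mean_H, lfc in rows:
        if mean_L <= 0 or mean_H <= 0:
            raise ValueError("reference means must be positive")
        implied.append(2.0**lfc / (mean_H / mean_L))
    return ScaleConstant(float(np.median(implied)))


def de_test(
    row_counts: np.ndarray, design: GroupDesign, library_totals: np.ndarray | None = None
) -> float:
    """Two-sided p-value of a pooled binomial proportion z-test.

    Replicates are pooled within group: with pooled counts k_H and k_L and
    group library totals N_H and N_L, tests k_H out of n = k_H + k_L
    against p0 = N_H / (N_H + N_L) using the score (null-variance) z.
    Returns 1.0 when the feature has no counts.
    """
    row_counts = np.asarray(row_counts, dtype=float)
    if np.any(row_counts < 0):
        raise ValueError("negative counts")
    if library_totals is None:
        library_totals = np.ones_like(row_counts)
    library_totals = np.asarray(library_totals, dtype=float)
    is_H = np.array([design.group_of[s] == "H" for s in design.sample_ids])
    k_H = row_counts[is_H].sum()
    k_L = row_counts[~is_H].sum()
    n = k_H + k_L
    if n == 0:
        return 1.0
    N_H = library_totals[is_H].sum()
    N_L = library_totals[~is_H].sum()
    p0 = N_H / (N_H + N_L)
    z = (k_H / n - p0) / math.sqrt(p0 * (1 - p0) / n)
    return float(2.0 * stats.norm.sf(abs(z)))


def bh_adjust(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_de(
    results: list[DEResult], fc_threshold: float = 2.0, q_threshold: float = 0.001
) -> list[DEResult]:
    """Apply the significance gate |log2FC| >= log2(fc) AND Q <= q (inclusive)."""
    lfc_cut = math.log2(fc_threshold)
    for r in results:
        r.significant = bool(abs(r.log2fc) >= lfc_cut and r.q <= q_threshold)
        if r.significant:
            r.direction = "Up" if r.log2fc > 0 else "Down"
        else:
            r.direction = "none"
    return results


def fpkm_bins(matrix: CountMatrix) -> dict[str, tuple[int, int, int]]:
    """Per-sample feature counts in the bins FPKM <= 1, 1 < FPKM < 10, FPKM >= 10."""
    if matrix.unit != "FPKM":
        raise ValueError("fpkm_bins expects an FPKM matrix")
    out: dict[str, tuple[int, int, int]] = {}
    for j, sample in enumerate(matrix.sample_ids):
        col = matrix.values[:, j]
        low = int(np.sum(col <= 1))
        high = int(np.sum(col >= 10))
        mid = col.size - low - high
        out[sample] = (low, mid, high)
    return out


def de_table(
    counts: CountMatrix,
    design: GroupDesign,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.001,
) -> list[DEResult]:
    """Full per-feature DE analysis of a raw count matrix.

    Tests on pooled raw counts against group library totals, computes
    log2FC from CPM-normalized group means (pseudo-expression floor for
    zeros), BH-adjusts, and applies the significance gate.
    """
    normed, _ = normalize(counts, design)
    is_H = np.array([design.group_of[s] == "H" for s in design.sample_ids])
    totals = counts.values.sum(axis=0)
    mean_L = normed.values[:, ~is_H].mean(axis=1)
    mean_H = normed.values[:, is_H].mean(axis=1)
    results = []
    for i, fid in enumerate(counts.feature_ids):
        p = de_test(counts.values[i], design, totals)
        mL = mean_L[i] if mean_L[i] > 0 else PSEUDO_EXPRESSION
        mH = mean_H[i] if mean_H[i] > 0 else PSEUDO_EXPRESSION
        results.append(
            DEResult(
                feature_id=fid,
                mean_L=float(mean_L[i]),
                mean_H=float(mean_H[i]),
                log2fc=log2_fold_change(mL, mH),
                p=p,
            )
        )
    qvals = bh_adjust([r.p for r in results])
    for r, q in zip(results, qvals):
        r.q = float(q)
    return call_de(results, fc_threshold, q_threshold)


def aggregate_by_gene(counts: CountMatrix, gene_of: dict[str, str]) -> CountMatrix:
    """Sum transcript counts by gene_id for gene-level testing."""
    genes: dict[str, np.ndarray] = {}
    order: list[str] = []
    for i, fid in enumerate(counts.feature_ids):
        gid = gene_of.get(fid, fid)
        if gid not in genes:
            genes[gid] = np.zeros(len(counts.sample_ids))
            order.append(gid)
        genes[gid] += counts.values[i]
    return CountMatrix(
        feature_ids=order,
        sample_ids=list(counts.sample_ids),
        values=np.vstack([genes[g] for g in order]) if order else np.zeros((0, len(counts.sample_ids))),
        unit=counts.unit,
    )
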