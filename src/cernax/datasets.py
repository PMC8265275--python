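"""Bundled reference data: published expression summaries used for calibration.

These small tables list the most abundant differentially expressed
lncRNAs, mRNAs and miRNAs from a chicken liver high-fat vs low-fat
RNA-seq comparison, each row carrying the two group expression values and
the published log2 fold change (H/L).  They serve as worked reference
input for :func:`cernax.diffexpr.fit_scale_from_reference`: the published
fold changes embed an undocumented between-library scale constant, which
the fit recovers (about 1.09 for the long-RNA libraries and 1.37 for the
small-RNA libraries), after which any held-out row's printed log2FC is
reproduced from its expression columns.

Each tuple is (feature_id, expression_L, expression_H, published_log2fc).
"""

from __future__ import annotations

__all__ = ["TOP_DEL_TABLE", "TOP_DEM_TABLE", "TOP_DES_TABLE", "rows_for_fit"]

# Top 10 abundant differentially expressed lncRNAs (read numbers, L and H).
TOP_DEL_TABLE: list[tuple[str, float, float, float]] = [
    ("LTCONS_00020831", 79374.24, 168343.7, 1.213923),
    ("LTCONS_00020832", 230312.4, 5371.91, -5.29276),
    ("LTCONS_00055244", 113243.0, 49591.0, -1.06202),
    ("LTCONS_00029013", 158164.8, 4411.57, -5.03474),
    ("LTCONS_00040763", 73239.73, 30631.24, -1.12837),
    ("LTCONS_00046846", 77193.92, 3376.17, -4.38577),
    ("LTCONS_00000249", 50129.79, 19380.0, -1.24184),
    ("LTCONS_00025768", 47501.63, 20827.96, -1.0602),
    ("LTCONS_00010452", 21954.88, 40581.95, 1.015552),
    ("LTCONS_00000621", 45945.24, 12643.59, -1.73225),
]

# Top 10 abundant differentially expressed mRNAs.
TOP_DEM_TABLE: list[tuple[str, float, float, float]] = [
    ("ENSGALT00000002892", 2165799.0, 592843.8, -1.73992),
    ("ENSGALT00000056823", 959658.0, 234419.0, -1.90418),
    ("MTCONS_00058597", 282406.2, 119824.5, -1.10759),
    ("ENSGALT00000083486", 371304.0, 112513.0, -1.59325),
    ("ENSGALT00000027531", 24398.34, 84566.61, 1.922561),
    ("ENSGALT00000019639", 168144.0, 70319.0, -1.12846),
    ("ENSGALT00000068577", 26347.0, 59925.02, 1.314775),
    ("MTCONS_00056041", 545124.6, 59193.44, -3.07382),
    ("ENSGALT00000024496", 159362.0, 58913.0, -1.30639),
    ("MTCONS_00043232", 132570.9, 58860.85, -1.04213),
]

# Top 20 abundant differentially expressed miRNAs (small-RNA libraries).
TOP_DES_TABLE: list[tuple[str, float, float, float]] = [
    ("miR-92a_1", 35074.0, 7418.0, -1.78953),
    ("miR-191-5p", 27280.33, 9062.833, -1.13806),
    ("miR-100-5p_1", 10997.17, 24209.0, 1.590181),
    ("miR-126-3p", 22141.0, 2196.833, -2.88145),
    ("miR-26c_1", 412.5, 21795.17, 6.17524),
    ("miR-126-3p_1", 2961.0, 17333.33, 3.001163),
    ("miR-92a_2", 1384.167, 17077.0, 4.076735),
    ("novel_mir182", 7226.5, 303.3333, -4.12255),
    ("miR-429", 2103.0, 4070.5, 1.404527),
    ("miR-125b_1", 2115.667, 3120.167, 1.012281),
    ("miR-10a-5p", 4031.0, 995.0, -1.5666),
    ("miR-24-3p", 3729.667, 1236.5, -1.14101),
    ("novel_mir4", 3346.167, 1189.333, -1.04059),
    ("let-7b", 3158.333, 1033.833, -1.15939),
    ("miR-146a_1", 3093.333, 716.6667, -1.65802),
    ("miR-140-5p_1", 1253.667, 2049.5, 1.160888),
    ("miR-146a-5p_1", 1103.667, 2170.167, 1.427271),
    ("miR-429_1", 3218.167, 42.16667, -5.80222),
    ("miR-10a_2", 638.8333, 2542.5, 2.444506),
    ("miR-103_1", 1747.5, 602.0, -1.08569),
]

#: canonical miR-24-3p mature sequence (5'->3') and the experimentally used
#: wild-type / mutated binding-site heptamers on its targets.
MIR_24_3P = "UGGCUCAGUUCAGCAGGAACAG"
MIR24_SITE_WT = "CUGAGCU"
MIR24_SITE_MUT = "GCACAUC"


def rows_for_fit(
    table: list[tuple[str, float, float, float]], held_out: str
) -> list[tuple[float, float, float]]:
    """All rows except ``held_out``, as (mean_L, mean_H, log2fc) triples."""
    rows = [(L, H, lfc) for fid, L, H, lfc in table if fid != held_out]
    if len(rows) == len(table):
        raise KeyError(f"{held_out!r} not in table")
    return rows
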