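"""End-to-end orchestration: classify -> diffexpr -> cis_target ->
mirna_target -> network_axis, with every gate threshold in one config.

Threshold defaults are the published gate values of the procedure being
implemented: |FC| >= 2, Q <= 0.001, both correlations >= 0.6, cis windows
10 kb upstream / 20 kb downstream, hybridization MFE <= -30 kcal/mol,
alignment MFE <= -45 kcal/mol, alignment score >= 300 on the external
tool scale (rescaled for the built-in scorer).  The run report records
the feature counts surviving each gate, mirroring the funnel a user
would see on their own data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cernax import core_io
from cernax.core_io import CountMatrix, GroupDesign, TranscriptRecord
from cernax.classify import builtin_coding_scores, vote_biotype
from cernax.diffexpr import DEResult, de_table, fpkm_bins
from cernax.cis_target import build_cis_pairs
from cernax.mirna_target import (
    EXTERNAL_PERFECT_SCORE,
    PERFECT_22MER_SCORE,
    MirnaSite,
    MirnaThresholds,
    scan_targets,
)
from cernax.network_axis import (
    AxisCandidate,
    RegulatoryNetwork,
    build_del_deg_networks,
    build_des_deg_network,
    nominate_axes,
    shared_genes,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunResult", "run_all", "run_from_data"]


@dataclass
class PipelineConfig:
    """Input paths and every gate threshold, defaulting to the published values."""

    annotation: str | None = None
    transcripts_fasta: str | None = None
    mirna_fasta: str | None = None
    counts: str | None = None
    mirna_counts: str | None = None
    design: str | None = None
    score_table: str | None = None  # optional external coding-potential scores
    outdir: str | None = None
    seed: int = 0

    fc_threshold: float = 2.0
    q_threshold: float = 0.001
    corr_threshold: float = 0.6
    up_window: int = 10_000
    down_window: int = 20_000
    hybrid_mfe: float = -30.0
    align_mfe: float = -45.0
    score_gate_external: float = 300.0
    trans_mfe: float = -30.0
    external_scores: bool = False  # score_table values are on external tool scales

    @property
    def score_gate_internal(self) -> float:
        return self.score_gate_external * PERFECT_22MER_SCORE / EXTERNAL_PERFECT_SCORE

    def mirna_thresholds(self) -> MirnaThresholds:
        gate = (
            self.score_gate_external if self.external_scores else self.score_gate_internal
        )
        return MirnaThresholds(
            score_gate=gate,
            align_mfe_gate=self.align_mfe,
            hybrid_mfe_gate=self.hybrid_mfe,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f: raw[f] for f in raw if f in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


@dataclass
class RunResult:
    """Everything one pipeline run produced."""

    biotype_of: dict[str, str]
    de_transcripts: list[DEResult]
    de_lnc: list[DEResult]
    de_mrna: list[DEResult]
    de_mirna: list[DEResult]
    fpkm: CountMatrix
    cis_pairs: list
    mirna_sites: list[MirnaSite]
    sponge_sites: list[MirnaSite]
    up_network: RegulatoryNetwork
    down_network: RegulatoryNetwork
    des_deg_network: RegulatoryNetwork
    shared: set[str]
    axes: list[AxisCandidate]
    report: dict


def _classify_transcripts(
    annotation: list[TranscriptRecord],
    sequences: dict[str, str],
    score_table: pd.DataFrame | None,
) -> dict[str, str]:
    """Resolve each transcript's biotype.

    Annotated biotypes are kept; unknowns are voted from an external
    score table when supplied, otherwise from the built-in scorer.
    Transcripts that cannot be scored (shorter than 200 nt) or whose
    vote splits 2-2 stay ambiguous and leave both downstream sets.
    """
    scores_by_id = {}
    if score_table is not None:
        for _, row in score_table.iterrows():
            scores_by_id[str(row["transcript_id"])] = (
                float(row["cpc"]), float(row["txcds"]), float(row["cnc"]),
                bool(int(row["pfam_hit"])),
            )
    out: dict[str, str] = {}
    for rec in annotation:
        if rec.biotype in ("mRNA", "lncRNA"):
            out[rec.transcript_id] = rec.biotype
            continue
        if rec.transcript_id in scores_by_id:
            cpc, txcds, cnc, pfam = scores_by_id[rec.transcript_id]
            from cernax.classify import CodingScores

            call = vote_biotype(CodingScores(cpc, txcds, cnc, pfam))
        else:
            seq = sequences.get(rec.transcript_id)
            if seq is None or len(seq) < 200:
                out[rec.transcript_id] = "ambiguous"
                continue
            call = vote_biotype(builtin_coding_scores(seq))
        out[rec.transcript_id] = call.biotype
    return out


def _fpkm_matrix(counts: CountMatrix, lengths: dict[str, int]) -> CountMatrix:
    lib = counts.values.sum(axis=0)
    lens = np.array([lengths[f] for f in counts.feature_ids], dtype=float)
    vals = counts.values * 1e9 / (lens[:, None] * lib[None, :])
    return CountMatrix(list(counts.feature_ids), list(counts.sample_ids), vals, unit="FPKM")


def run_from_data(
    annotation: list[TranscriptRecord],
    sequences: dict[str, str],
    mirna_sequences: dict[str, str],
    counts: CountMatrix,
    mirna_counts: CountMatrix,
    design: GroupDesign,
    config: PipelineConfig | None = None,
    score_table: pd.DataFrame | None = None,
) -> RunResult:
    """Run the full discovery pipeline on in-memory inputs."""
    cfg = config or PipelineConfig()
    report: dict = {"thresholds": {
        "fc": cfg.fc_threshold, "q": cfg.q_threshold, "corr": cfg.corr_threshold,
        "up_window": cfg.up_window, "down_window": cfg.down_window,
        "hybrid_mfe": cfg.hybrid_mfe, "align_mfe": cfg.align_mfe,
        "score_gate": cfg.score_gate_external
        if cfg.external_scores else round(cfg.score_gate_internal, 4),
    }, "seed": cfg.seed}

    # stage 1: biotype classification
    biotype_of = _classify_transcripts(annotation, sequences, score_table)
    annotation = [
        TranscriptRecord(
            r.transcript_id, r.gene_id, r.chrom, r.strand, r.start, r.end,
            biotype=biotype_of[r.transcript_id], novel=r.novel,
        )
        for r in annotation
    ]
    n_mrna = sum(1 for b in biotype_of.values() if b == "mRNA")
    n_lnc = sum(1 for b in biotype_of.values() if b == "lncRNA")
    report["classify"] = {
        "transcripts": len(annotation), "mRNA": n_mrna, "lncRNA": n_lnc,
        "ambiguous": len(annotation) - n_mrna - n_lnc,
    }

    # stage 2: differential expression (transcripts and miRNAs separately)
    de_transcripts = de_table(counts, design, cfg.fc_threshold, cfg.q_threshold)
    de_lnc = [r for r in de_transcripts if biotype_of.get(r.feature_id) == "lncRNA"]
    de_mrna = [r for r in de_transcripts if biotype_of.get(r.feature_id) == "mRNA"]
    de_mirna = de_table(mirna_counts, design, cfg.fc_threshold, cfg.q_threshold)
    report["diffexpr"] = {
        "DEL": sum(r.significant for r in de_lnc),
        "DEM": sum(r.significant for r in de_mrna),
        "DES": sum(r.significant for r in de_mirna),
    }
    logger.info("DE gate: %s", report["diffexpr"])

    # stage 3: cis target pairs with the dual correlation gate
    lengths = {r.transcript_id: r.length for r in annotation}
    fpkm = _fpkm_matrix(counts, lengths)
    report["fpkm_bins"] = {s: list(b) for s, b in fpkm_bins(fpkm).items()}
    cis_pairs = build_cis_pairs(
        annotation, fpkm, de_lnc, de_mrna,
        cfg.up_window, cfg.down_window, cfg.corr_threshold,
    )
    report["cis"] = {
        "pairs": len(cis_pairs),
        "pairs_with_DE_mrna": sum(p.mrna_is_de for p in cis_pairs),
    }

    # stage 4: miRNA target scanning (DE miRNAs vs mRNAs, then DE lncRNAs)
    thr = cfg.mirna_thresholds()
    sig_mirna = [r for r in de_mirna if r.significant]
    mrna_ids = [r.transcript_id for r in annotation if r.biotype == "mRNA"]
    sig_lnc_ids = [r.feature_id for r in de_lnc if r.significant]
    mirna_sites: list[MirnaSite] = []
    for mres in sig_mirna:
        mseq = mirna_sequences[mres.feature_id]
        for tid in mrna_ids:
            mirna_sites.extend(
                scan_targets(mseq, sequences[tid], thr, mres.feature_id, tid)
            )
    sponge_sites: list[MirnaSite] = []
    for mres in sig_mirna:
        mseq = mirna_sequences[mres.feature_id]
        for tid in sig_lnc_ids:
            sponge_sites.extend(
                scan_targets(mseq, sequences[tid], thr, mres.feature_id, tid)
            )
    report["mirna_target"] = {
        "candidate_sites": len(mirna_sites),
        "passing_sites": sum(s.passes for s in mirna_sites),
        "passing_sponge_sites": sum(s.passes for s in sponge_sites),
    }

    # stage 5: networks, intersection, axis nomination
    up_net, down_net = build_del_deg_networks(cis_pairs, de_lnc, de_mrna)
    des_net = build_des_deg_network(mirna_sites, de_mirna, de_mrna)
    cis_targets = up_net.targets() | down_net.targets()
    shared = cis_targets & des_net.targets()
    axes = nominate_axes(
        shared, cis_pairs, mirna_sites, sponge_sites, de_lnc, de_mirna, de_mrna
    )
    report["network_axis"] = {
        "up_edges": len(up_net.edges), "down_edges": len(down_net.edges),
        "des_deg_edges": len(des_net.edges),
        "negative_pairs": sum(1 for e in des_net.edges if e[3] == "negative"),
        "positive_pairs": sum(1 for e in des_net.edges if e[3] == "positive"),
        "shared_genes": sorted(shared),
        "axes": [[a.lnc_id, a.mirna_id, a.gene_id] for a in axes],
        "consistent_axes": [
            [a.lnc_id, a.mirna_id, a.gene_id] for a in axes if a.consistent
        ],
    }
    result = RunResult(
        biotype_of=biotype_of, de_transcripts=de_transcripts, de_lnc=de_lnc,
        de_mrna=de_mrna, de_mirna=de_mirna, fpkm=fpkm, cis_pairs=cis_pairs,
        mirna_sites=mirna_sites, sponge_sites=sponge_sites, up_network=up_net,
        down_network=down_net, des_deg_network=des_net, shared=shared,
        axes=axes, report=report,
    )
    if cfg.outdir:
        _write_outputs(result, Path(cfg.outdir))
    return result


def run_all(config: PipelineConfig) -> RunResult:
    """Load the configured inputs and run the full pipeline."""
    for key in ("annotation", "transcripts_fasta", "mirna_fasta", "counts",
                "mirna_counts", "design"):
        if getattr(config, key) is None:
            raise ValueError(f"config is missing the {key} path")
    try:
        design = GroupDesign.from_table(config.design)
        annotation = core_io.read_annotation(config.annotation)
        sequences = core_io.read_sequences(config.transcripts_fasta)
        mirna_sequences = core_io.read_sequences(config.mirna_fasta, rna=True)
        counts = core_io.read_expression(config.counts, design)
        mirna_counts = core_io.read_expression(config.mirna_counts, design)
        score_table = (
            pd.read_csv(config.score_table, sep="\t") if config.score_table else None
        )
    except Exception as exc:
        raise RuntimeError(f"input stage failed: {exc}") from exc
    return run_from_data(
        annotation, sequences, mirna_sequences, counts, mirna_counts, design,
        config, score_table,
    )


def _de_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id, "mean_L": r.mean_L, "mean_H": r.mean_H,
                "log2FC": r.log2fc, "p": r.p, "q": r.q,
                "direction": r.direction, "significant": r.significant,
            }
            for r in results
        ]
    ).sort_values("feature_id").reset_index(drop=True)


def _write_outputs(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.6f"
    _de_frame(result.de_transcripts).to_csv(
        outdir / "de_transcripts.tsv", sep="\t", index=False, float_format=fmt
    )
    _de_frame(result.de_mirna).to_csv(
        outdir / "de_mirna.tsv", sep="\t", index=False, float_format=fmt
    )
    pd.DataFrame(
        [
            {
                "lnc_id": p.lnc_id, "mrna_id": p.mrna_id, "relation": p.relation,
                "distance": p.distance, "pearson": p.pearson,
                "spearman": p.spearman, "mrna_is_DE": p.mrna_is_de,
            }
            for p in result.cis_pairs
        ]
    ).to_csv(outdir / "cis_pairs.tsv", sep="\t", index=False, float_format=fmt)
    pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id, "target_id": s.target_id,
                "start": s.target_start, "end": s.target_end,
                "seed_class": s.seed_class, "align_score": s.align_score,
                "align_mfe": s.align_mfe, "hybrid_mfe": s.hybrid_mfe,
                "passes": s.passes,
            }
            for s in sorted(
                result.mirna_sites + result.sponge_sites,
                key=lambda s: (s.mirna_id, s.target_id, s.target_start),
            )
        ]
    ).to_csv(outdir / "mirna_sites.tsv", sep="\t", index=False, float_format=fmt)
    de_index = {r.feature_id: r for r in result.de_transcripts + result.de_mirna}

    def node_table(net: RegulatoryNetwork) -> pd.DataFrame:
        rows = []
        for node in sorted(net.node_kind):
            r = de_index.get(node)
            rows.append({
                "id": node, "kind": net.node_kind[node],
                "log2FC": round(r.log2fc, 6) if r else "",
                "direction": r.direction if r else "none",
            })
        return pd.DataFrame(rows, columns=["id", "kind", "log2FC", "direction"])

    core_io.write_network(result.up_network, node_table(result.up_network),
                          outdir / "network_up")
    core_io.write_network(result.down_network, node_table(result.down_network),
                          outdir / "network_down")
    core_io.write_network(result.des_deg_network, node_table(result.des_deg_network),
                          outdir / "network_des_deg")
    with open(outdir / "axes.json", "w") as fh:
        json.dump(
            [
                {
                    "lnc_id": a.lnc_id, "mirna_id": a.mirna_id, "gene_id": a.gene_id,
                    "pattern": list(a.pattern), "consistent": a.consistent,
                    "combined_abs_log2fc": round(a.combined_lfc, 6),
                    "sponge_site": [
                        a.evidence["sponge_site"].target_start,
                        a.evidence["sponge_site"].target_end,
                    ],
                    "gene_site": [
                        a.evidence["mirna_gene_site"].target_start,
                        a.evidence["mirna_gene_site"].target_end,
                    ],
                }
                for a in result.axes
            ],
            fh, indent=1, sort_keys=True,
        )
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=1, sort_keys=True)
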