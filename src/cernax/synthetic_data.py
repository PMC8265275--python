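"""Seeded generator of synthetic annotation, sequences and counts with a
planted truth set.

The generator emulates the study design the pipeline assumes: a 6-vs-6
two-group (L/H) liver RNA-seq contrast with transcript-level counts,
lncRNAs positioned near protein-coding neighbours with planted
co-expression, and miRNA seed sites spliced into 3'UTRs and
sponge-lncRNA sequences.  Counts are negative-binomial around per-sample
means; each feature carries a lognormal per-sample biological factor,
and a planted cis lncRNA's counts ride on its partner gene's realized
counts (times lognormal noise), which is what produces the
above-threshold Pearson/Spearman co-expression.  Planted DE features
receive a 2**lfc_magnitude group shift.  Decoys exercise every gate:
near-window lncRNAs (gap exactly one nt beyond the window),
low-correlation neighbours, shared genes without sponge sites, and
scrambled-seed sponge sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from cernax.core_io import (
    CountMatrix,
    GroupDesign,
    TranscriptRecord,
    write_annotation,
    write_expression,
    write_sequences,
)
from cernax.classify import builtin_coding_scores, vote_biotype
from cernax.mirna_target import seed_match_positions

__all__ = ["SimulationParams", "TruthSet", "SimulatedData", "simulate", "evaluate_recovery"]

_COMP_DNA = {"A": "T", "T": "A", "G": "C", "C": "G"}

# codon pool with strong positional bias (and no stop codons), so generated
# coding sequences read as coding to position-asymmetry statistics
_CODONS = ["GAC", "GAG", "GCC", "GCT", "AAG", "AAC", "ATC", "CTG", "GTG",
           "TTC", "GGC", "GAT", "CAG", "ACC", "TAC"]
_CODON_P = np.array([0.12, 0.12, 0.10, 0.06, 0.10, 0.08, 0.06, 0.08, 0.06,
                     0.04, 0.06, 0.04, 0.04, 0.02, 0.02])
_CODON_P = _CODON_P / _CODON_P.sum()


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults are the study conditions being emulated."""

    n_genes: int = 200
    n_lnc: int = 50
    n_mirna: int = 30
    samples_per_group: int = 6
    de_fraction: float = 0.15
    lfc_magnitude: float = 2.0
    nb_dispersion: float = 0.05
    coexpr_noise_sd: float = 0.2
    planted_axes: int = 1
    decoy_shared_genes: int = 5
    near_window_decoys: int = 3
    low_corr_decoys: int = 3
    scrambled_site_decoys: int = 3
    mean_count: float = 500.0
    biological_cv_sd: float = 0.3
    up_window: int = 10_000
    down_window: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_lnc", "n_mirna", "samples_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.de_fraction < 1):
            raise ValueError("de_fraction must lie in [0, 1)")
        need = (self.planted_axes + self.decoy_shared_genes
                + self.near_window_decoys + self.low_corr_decoys
                + self.scrambled_site_decoys)
        if need > self.n_lnc:
            raise ValueError("not enough lncRNAs for the requested planted structure")
        if self.planted_axes + self.decoy_shared_genes + self.near_window_decoys + self.low_corr_decoys > self.n_genes:
            raise ValueError("not enough genes for the requested planted structure")


@dataclass
class TruthSet:
    """Ground truth of every planted element, keyed by generated ids."""

    de_features: dict[str, str] = field(default_factory=dict)  # id -> Up/Down
    cis_pairs: set[tuple[str, str]] = field(default_factory=set)  # (lnc, mrna)
    near_window_decoys: set[tuple[str, str]] = field(default_factory=set)
    low_corr_decoys: set[tuple[str, str]] = field(default_factory=set)
    mirna_sites: set[tuple[str, str]] = field(default_factory=set)  # (mirna, target)
    sponge_sites: set[tuple[str, str]] = field(default_factory=set)  # (lnc, mirna)
    scrambled_decoys: set[tuple[str, str]] = field(default_factory=set)
    axes: list[tuple[str, str, str]] = field(default_factory=list)  # (lnc, mirna, gene)

    def to_json(self) -> str:
        d = {
            "de_features": self.de_features,
            "cis_pairs": sorted(self.cis_pairs),
            "near_window_decoys": sorted(self.near_window_decoys),
            "low_corr_decoys": sorted(self.low_corr_decoys),
            "mirna_sites": sorted(self.mirna_sites),
            "sponge_sites": sorted(self.sponge_sites),
            "scrambled_decoys": sorted(self.scrambled_decoys),
            "axes": sorted(self.axes),
        }
        return json.dumps(d, indent=1, sort_keys=True)


@dataclass
class SimulatedData:
    """In-memory result of one simulation run."""

    params: SimulationParams
    annotation: list[TranscriptRecord]
    sequences: dict[str, str]        # transcript id -> DNA sequence
    mirna_sequences: dict[str, str]  # miRNA id -> RNA sequence
    counts: CountMatrix              # transcripts (mRNA + lncRNA)
    mirna_counts: CountMatrix
    design: GroupDesign
    truth: TruthSet

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation": outdir / "annotation.gtf",
            "transcripts": outdir / "transcripts.fa",
            "mirnas": outdir / "mirnas.fa",
            "counts": outdir / "counts.tsv",
            "mirna_counts": outdir / "mirna_counts.tsv",
            "design": outdir / "design.tsv",
            "truth": outdir / "truth.json",
        }
        write_annotation(self.annotation, paths["annotation"])
        write_sequences(self.sequences, paths["transcripts"])
        write_sequences(self.mirna_sequences, paths["mirnas"])
        write_expression(self.counts, paths["counts"])
        write_expression(self.mirna_counts, paths["mirna_counts"])
        with open(paths["design"], "w") as fh:
            fh.write("sample_id\tgroup\n")
            for s in self.design.sample_ids:
                fh.write(f"{s}\t{self.design.group_of[s]}\n")
        with open(paths["truth"], "w") as fh:
            fh.write(self.truth.to_json())
        return paths


def _random_seq(rng: np.random.Generator, length: int, p=(0.3, 0.2, 0.2, 0.3)) -> str:
    return "".join(rng.choice(["A", "C", "G", "T"], size=length, p=p))


def _revcomp_dna(seq: str) -> str:
    return "".join(_COMP_DNA[b] for b in reversed(seq.replace("U", "T")))


def _make_coding_seq(rng: np.random.Generator, length: int) -> str:
    """A transcript with a long, codon-biased ORF that the built-in
    coding-potential vote classifies as mRNA."""
    for _ in range(50):
        utr5 = _random_seq(rng, 30)
        n_codons = max(170, int(length * 0.6) // 3)
        cds = "ATG" + "".join(rng.choice(_CODONS, size=n_codons, p=_CODON_P)) + "TAA"
        utr3_len = max(60, length - len(utr5) - len(cds))
        utr3 = _random_seq(rng, utr3_len)
        seq = utr5 + cds + utr3
        if vote_biotype(builtin_coding_scores(seq)).biotype == "mRNA":
            return seq
    raise RuntimeError("failed to generate a coding-like sequence")


def _make_noncoding_seq(rng: np.random.Generator, length: int) -> str:
    """A transcript without substantial ORFs (classified lncRNA)."""
    length = max(250, length)
    for _ in range(200):
        seq = _random_seq(rng, length, p=(0.32, 0.18, 0.18, 0.32))
        if vote_biotype(builtin_coding_scores(seq)).biotype == "lncRNA":
            return seq
    raise RuntimeError("failed to generate a noncoding-like sequence")


def _make_mirna(rng: np.random.Generator) -> str:
    while True:
        seq = "".join(rng.choice(["A", "C", "G", "U"], size=22, p=(0.2, 0.28, 0.28, 0.24)))
        gc = (seq.count("G") + seq.count("C")) / 22
        if 0.5 <= gc <= 0.7:
            return seq


def _splice_site(seq: str, site_dna: str, pos: int) -> str:
    return seq[:pos] + site_dna + seq[pos + len(site_dna):]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with Var = mu + dispersion * mu^2."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-8)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def simulate(params: SimulationParams, seed: int | None = None) -> SimulatedData:
    """Generate one synthetic dataset with its truth set.

    All randomness derives from a single seed (``seed`` overrides
    ``params.seed``) through spawned child generators, so identical calls
    are byte-identical after writing.
    """
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    (seq_rng, layout_rng, expr_rng) = [np.random.default_rng(s) for s in root.spawn(3)]
    truth = TruthSet()
    n_per_chrom = 20
    genome_spacing = 100_000

    # --- sample design ------------------------------------------------------
    n = params.samples_per_group
    sample_ids = [f"L{i+1}" for i in range(n)] + [f"H{i+1}" for i in range(n)]
    design = GroupDesign(
        tuple(sample_ids), {s: ("L" if s.startswith("L") else "H") for s in sample_ids}
    )
    is_H = np.array([g == "H" for g in (design.group_of[s] for s in sample_ids)])

    # --- gene placement and sequences --------------------------------------
    genes: list[TranscriptRecord] = []
    sequences: dict[str, str] = {}
    for g in range(params.n_genes):
        chrom = f"chr{g // n_per_chrom + 1}"
        start = (g % n_per_chrom) * genome_spacing + 50_001
        length = int(layout_rng.integers(900, 2000))
        strand = "+" if layout_rng.random() < 0.5 else "-"
        tid = f"MRNA_{g:04d}"
        genes.append(
            TranscriptRecord(tid, f"GENE_{g:04d}", chrom, strand, start,
                             start + length - 1, biotype="unknown", novel=True)
        )
        sequences[tid] = _make_coding_seq(seq_rng, length)

    # --- lncRNA roles -------------------------------------------------------
    roles: list[tuple[str, int]] = []  # (role, partner gene index)
    gene_cursor = 0
    for _ in range(params.planted_axes):
        roles.append(("axis", gene_cursor)); gene_cursor += 1
    for _ in range(params.decoy_shared_genes):
        roles.append(("decoy_shared", gene_cursor)); gene_cursor += 1
    for _ in range(params.near_window_decoys):
        roles.append(("near_window", gene_cursor)); gene_cursor += 1
    for _ in range(params.low_corr_decoys):
        roles.append(("low_corr", gene_cursor)); gene_cursor += 1
    for _ in range(params.scrambled_site_decoys):
        roles.append(("scrambled", -1))
    while len(roles) < params.n_lnc:
        roles.append(("background", -1))

    lncs: list[TranscriptRecord] = []
    for i, (role, gidx) in enumerate(roles):
        tid = f"LNC_{i:04d}"
        length = int(layout_rng.integers(400, 1200))
        if gidx >= 0:
            gene = genes[gidx]
            if role == "near_window":
                gap = params.up_window + 1  # one nt beyond the cis window
            else:
                gap = int(layout_rng.integers(500, params.up_window - 500))
            # place on the gene's 5' (upstream) side
            if gene.strand == "+":
                end = gene.start - gap
                start = end - length + 1
            else:
                start = gene.end + gap
                end = start + length - 1
            chrom, strand = gene.chrom, gene.strand
        else:
            chrom = "chrU"
            start = i * 50_000 + 10_001
            end = start + length - 1
            strand = "+" if layout_rng.random() < 0.5 else "-"
        lncs.append(TranscriptRecord(tid, f"LGENE_{i:04d}", chrom, strand,
                                     start, end, biotype="unknown", novel=True))
        sequences[tid] = _make_noncoding_seq(seq_rng, length)

    # --- miRNAs -------------------------------------------------------------
    mirna_ids = [f"MIR_{i:03d}" for i in range(params.n_mirna)]
    mirna_seqs = {m: _make_mirna(seq_rng) for m in mirna_ids}

    # --- differential expression assignment ---------------------------------
    # planted structure first, then background features at de_fraction
    lfc = params.lfc_magnitude
    de_dir: dict[str, str] = {}
    axis_mirnas: list[str] = []
    decoy_mirnas: list[str] = []
    mir_cursor = 0
    for k, (role, gidx) in enumerate(roles):
        lnc_id = f"LNC_{k:04d}"
        if role == "axis":
            gene = genes[gidx]
            m = mirna_ids[mir_cursor]; mir_cursor += 1
            axis_mirnas.append(m)
            de_dir[gene.transcript_id] = "Up"
            de_dir[lnc_id] = "Up"
            de_dir[m] = "Down"
            truth.cis_pairs.add((lnc_id, gene.transcript_id))
            truth.mirna_sites.add((m, gene.transcript_id))
            truth.sponge_sites.add((lnc_id, m))
            truth.axes.append((lnc_id, m, gene.transcript_id))
        elif role == "decoy_shared":
            gene = genes[gidx]
            # two dedicated decoy miRNAs are enough for all decoy genes
            if len(decoy_mirnas) < 2:
                m = mirna_ids[mir_cursor]; mir_cursor += 1
                decoy_mirnas.append(m)
            else:
                m = decoy_mirnas[gidx % 2]
            d = "Up" if layout_rng.random() < 0.5 else "Down"
            de_dir[gene.transcript_id] = d
            de_dir[lnc_id] = d
            de_dir.setdefault(m, "Down" if layout_rng.random() < 0.5 else "Up")
            truth.cis_pairs.add((lnc_id, gene.transcript_id))
            truth.mirna_sites.add((m, gene.transcript_id))
        elif role == "near_window":
            gene = genes[gidx]
            de_dir[lnc_id] = "Up"
            truth.near_window_decoys.add((lnc_id, gene.transcript_id))
        elif role == "low_corr":
            gene = genes[gidx]  # host gene stays non-DE
            de_dir[lnc_id] = "Up" if layout_rng.random() < 0.5 else "Down"
            truth.low_corr_decoys.add((lnc_id, gene.transcript_id))
        elif role == "scrambled":
            m = axis_mirnas[k % len(axis_mirnas)] if axis_mirnas else mirna_ids[0]
            truth.scrambled_decoys.add((lnc_id, m))

    planted_gene_ids = {genes[gidx].transcript_id for role, gidx in roles if gidx >= 0}
    background_genes = [g.transcript_id for g in genes if g.transcript_id not in planted_gene_ids]
    for tid in background_genes:
        if layout_rng.random() < params.de_fraction:
            de_dir[tid] = "Up" if layout_rng.random() < 0.5 else "Down"
    for k, (role, _g) in enumerate(roles):
        tid = f"LNC_{k:04d}"
        if role in ("background", "scrambled") and layout_rng.random() < params.de_fraction:
            de_dir[tid] = "Up" if layout_rng.random() < 0.5 else "Down"
    for m in mirna_ids:
        if m not in de_dir and layout_rng.random() < params.de_fraction:
            de_dir[m] = "Up" if layout_rng.random() < 0.5 else "Down"
    truth.de_features = dict(de_dir)

    # --- plant miRNA sites in sequences -------------------------------------
    def plant(target_id: str, mirna_id: str, scrambled: bool = False) -> None:
        mseq = mirna_seqs[mirna_id]
        site = _revcomp_dna(mseq)  # exact antiparallel complement, 22 nt
        if scrambled:
            site_list = list(site)
            host = sequences[target_id]
            pos = len(host) - 40
            for _ in range(100):
                seq_rng.shuffle(site_list)
                cand = "".join(site_list)
                planted = _splice_site(host, cand, pos)
                # no residual seed in or around the scrambled site
                if not seed_match_positions(mseq, planted[max(0, pos - 6): pos + len(cand) + 6]):
                    sequences[target_id] = planted
                    return
            raise RuntimeError("could not scramble a site without a residual seed")
        host = sequences[target_id]
        pos = len(host) - 40  # inside the 3' end (3'UTR for mRNAs)
        sequences[target_id] = _splice_site(host, site, pos)

    for m, tid in truth.mirna_sites:
        plant(tid, m)
    for lnc_id, m in truth.sponge_sites:
        plant(lnc_id, m)
    for lnc_id, m in truth.scrambled_decoys:
        plant(lnc_id, m, scrambled=True)

    # --- expression ----------------------------------------------------------
    n_samples = 2 * n
    depth = np.exp(expr_rng.normal(0.0, 0.15, size=n_samples))

    def group_shift(fid: str) -> np.ndarray:
        d = de_dir.get(fid)
        if d is None:
            return np.ones(n_samples)
        fold = 2.0 ** (lfc if d == "Up" else -lfc)
        return np.where(is_H, fold, 1.0)

    def base_mean(rng: np.random.Generator) -> float:
        return float(np.exp(rng.normal(np.log(params.mean_count), 0.7)))

    counts_rows: dict[str, np.ndarray] = {}
    gene_realized: dict[str, np.ndarray] = {}
    for rec in genes:
        mu = (base_mean(expr_rng)
              * np.exp(expr_rng.normal(0.0, params.biological_cv_sd, size=n_samples))
              * group_shift(rec.transcript_id) * depth)
        row = _nb_draw(expr_rng, mu, params.nb_dispersion)
        counts_rows[rec.transcript_id] = row
        gene_realized[rec.transcript_id] = row / depth

    cis_partner = {lnc: gene for lnc, gene in truth.cis_pairs}
    for k, rec in enumerate(lncs):
        tid = rec.transcript_id
        partner = cis_partner.get(tid)
        if partner is not None:
            # ride the partner's realized expression: co-expression by design
            ratio = 0.5 * base_mean(expr_rng) / params.mean_count
            mu = (np.maximum(gene_realized[partner], 1.0) * ratio
                  * np.exp(expr_rng.normal(0.0, params.coexpr_noise_sd, size=n_samples))
                  * depth)
        else:
            mu = (base_mean(expr_rng)
                  * np.exp(expr_rng.normal(0.0, params.biological_cv_sd, size=n_samples))
                  * group_shift(tid) * depth)
        counts_rows[tid] = _nb_draw(expr_rng, mu, params.nb_dispersion)

    mirna_rows: dict[str, np.ndarray] = {}
    for m in mirna_ids:
        mu = (base_mean(expr_rng)
              * np.exp(expr_rng.normal(0.0, params.biological_cv_sd, size=n_samples))
              * group_shift(m) * depth)
        mirna_rows[m] = _nb_draw(expr_rng, mu, params.nb_dispersion)

    feature_order = [g.transcript_id for g in genes] + [l.transcript_id for l in lncs]
    counts = CountMatrix(
        feature_ids=feature_order,
        sample_ids=sample_ids,
        values=np.vstack([counts_rows[f] for f in feature_order]),
        unit="count",
    )
    mirna_counts = CountMatrix(
        feature_ids=list(mirna_ids),
        sample_ids=sample_ids,
        values=np.vstack([mirna_rows[m] for m in mirna_ids]),
        unit="count",
    )
    return SimulatedData(
        params=params,
        annotation=genes + lncs,
        sequences=sequences,
        mirna_sequences=mirna_seqs,
        counts=counts,
        mirna_counts=mirna_counts,
        design=design,
        truth=truth,
    )


def _prf(predicted: set, actual: set) -> dict:
    tp = len(predicted & actual)
    sensitivity = tp / len(actual) if actual else None
    precision = tp / len(predicted) if predicted else None
    return {"tp": tp, "n_true": len(actual), "n_pred": len(predicted),
            "sensitivity": sensitivity, "precision": precision}


def evaluate_recovery(
    truth: TruthSet,
    de_called: dict[str, str] | None = None,
    cis_pairs: set[tuple[str, str]] | None = None,
    mirna_sites: set[tuple[str, str]] | None = None,
    axes: list[tuple[str, str, str]] | None = None,
) -> dict:
    """Per-stage confusion summaries of pipeline outputs against the truth.

    Any stage passed as None is skipped.  DE recovery requires the correct
    direction, not just the call.
    """
    metrics: dict = {}
    if de_called is not None:
        pred = {(f, d) for f, d in de_called.items()}
        actual = {(f, d) for f, d in truth.de_features.items()}
        metrics["de"] = _prf(pred, actual)
    if cis_pairs is not None:
        metrics["cis"] = _prf(set(cis_pairs), set(truth.cis_pairs))
    if mirna_sites is not None:
        metrics["mirna_targets"] = _prf(set(mirna_sites), set(truth.mirna_sites))
    if axes is not None:
        metrics["axes"] = _prf(set(axes), set(truth.axes))
    return metrics
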