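"""Readers and writers for the external formats the pipeline touches.

Coordinates are 1-based and inclusive throughout (GTF convention); any
half-open arithmetic is internal to an operation and never surfaced.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from cernax.network_axis import RegulatoryNetwork

logger = logging.getLogger(__name__)

_IUPAC_NT = set("ACGTUNRYSWKMBDHV")
_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class TranscriptRecord:
    """A located transcript; the unit of all interval logic.

    ``start``/``end`` are 1-based inclusive nucleotide positions with
    ``end >= start``; ``biotype`` is one of ``mRNA``, ``lncRNA`` or
    ``unknown`` (resolved later by the classify stage).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "unknown"
    novel: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.transcript_id}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid span [{self.start}, {self.end}] for {self.transcript_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of samples to the two contrasted groups L (low) and H (high)."""

    sample_ids: tuple[str, ...]
    group_of: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "group_of", dict(self.group_of))
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in design")
        for s in self.sample_ids:
            if self.group_of.get(s) not in ("L", "H"):
                raise ValueError(f"sample {s!r} not assigned to group L or H")
        groups = {self.group_of[s] for s in self.sample_ids}
        if groups != {"L", "H"}:
            raise ValueError("both groups L and H must be non-empty")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]

    @classmethod
    def from_table(cls, path: str | Path) -> "GroupDesign":
        """Read a two-column TSV (sample_id, group) with a header row."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(tuple(df.iloc[:, 0]), dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


@dataclass
class CountMatrix:
    """Feature-by-sample matrix of read counts or FPKM, plus its design."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: str = "count"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("matrix dimensions inconsistent with labels")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.any(self.values < 0):
            raise ValueError("negative values in matrix")
        if self.unit not in ("count", "FPKM"):
            raise ValueError(f"unknown unit {self.unit!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]


def read_annotation(path: str | Path) -> list[TranscriptRecord]:
    """Parse a GTF file into one record per ``transcript_id``.

    Exon lines of one transcript are merged to the transcript span
    (min start, max end).  A ``biotype`` (or ``transcript_biotype``/
    ``gene_biotype``) attribute is honoured when present; otherwise the
    biotype stays ``unknown``.  Lines whose transcript re-appears on a
    different chromosome or strand raise an error.
    """
    spans: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 fields")
            chrom, _source, _feature, start_s, end_s, _score, strand, _frame, attrs = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"malformed GTF line {lineno}: bad coordinates") from exc
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            if tid is None:
                continue  # gene-level or header-like line
            gid = attr.get("gene_id", tid)
            biotype = (
                attr.get("transcript_biotype")
                or attr.get("gene_biotype")
                or attr.get("biotype")
                or "unknown"
            )
            novel = attr.get("novel", "0") in ("1", "true", "True")
            if tid not in spans:
                spans[tid] = dict(
                    gene_id=gid, chrom=chrom, strand=strand,
                    start=start, end=end, biotype=biotype, novel=novel,
                )
                order.append(tid)
            else:
                rec = spans[tid]
                if rec["chrom"] != chrom or rec["strand"] != strand:
                    raise ValueError(
                        f"GTF line {lineno}: transcript {tid} has conflicting "
                        f"chromosome/strand"
                    )
                rec["start"] = min(rec["start"], start)
                rec["end"] = max(rec["end"], end)
                if biotype != "unknown":
                    rec["biotype"] = biotype
    return [TranscriptRecord(transcript_id=t, **spans[t]) for t in order]


def write_annotation(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write records as single-line transcript features (round-trips spans)."""
    with open(path, "w") as fh:
        for r in records:
            attrs = (
                f'gene_id "{r.gene_id}"; transcript_id "{r.transcript_id}"; '
                f'biotype "{r.biotype}"; novel "{1 if r.novel else 0}";'
            )
            fh.write(
                f"{r.chrom}\tcernax\ttranscript\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )


def read_sequences(path: str | Path, rna: bool = False) -> dict[str, str]:
    """Read a FASTA file into an id → sequence map.

    Ids are truncated at the first whitespace; sequences are uppercased and,
    with ``rna=True``, T is converted to U for RNA-context consumers.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        if sid in seqs:
            raise ValueError(f"duplicate FASTA id {sid!r}")
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in _IUPAC_NT:
                raise ValueError(
                    f"non-IUPAC character {ch!r} at position {i + 1} of record {sid!r}"
                )
        if rna:
            seq = seq.replace("T", "U")
        seqs[sid] = seq
    return seqs


def write_sequences(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_expression(path: str | Path, design: GroupDesign, unit: str = "count") -> CountMatrix:
    """Read a feature-by-sample TSV; columns are reordered to the design.

    Extra (unlisted) sample columns are dropped with a warning; a missing
    design sample or any negative value is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s for s in design.sample_ids if s not in df.columns]
    if missing:
        raise ValueError(f"expression table missing sample columns: {missing}")
    extra = [c for c in df.columns if c not in design.sample_ids]
    if extra:
        logger.warning("dropping %d sample columns not in design: %s", len(extra), extra)
    df = df[list(design.sample_ids)]
    return CountMatrix(
        feature_ids=[str(i) for i in df.index],
        sample_ids=list(design.sample_ids),
        values=df.to_numpy(dtype=float),
        unit=unit,
    )


def write_expression(matrix: CountMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="feature_id", float_format="%.6f")


def write_network(
    network: "RegulatoryNetwork",
    node_attrs: pd.DataFrame | None,
    prefix: str | Path,
) -> tuple[Path, Path]:
    """Export a network as a SIF edge file plus a node-attribute TSV.

    Rows are ordered lexicographically so repeated exports of the same
    network are byte-identical.  Returns the two paths written.
    """
    prefix = Path(prefix)
    for src, _kind, tgt, _sign in network.edges:
        if src not in network.node_kind or tgt not in network.node_kind:
            raise ValueError(f"edge references unknown node: {src} or {tgt}")
    sif_path = prefix.with_suffix(".sif")
    attr_path = Path(str(prefix) + "_nodes.tsv")
    rows = sorted((src, kind, tgt) for src, kind, tgt, _sign in network.edges)
    with open(sif_path, "w") as fh:
        for src, kind, tgt in rows:
            fh.write(f"{src} {kind} {tgt}\n")
    if node_attrs is None:
        node_attrs = pd.DataFrame(
            {"id": sorted(network.node_kind), "kind": [network.node_kind[n] for n in sorted(network.node_kind)]}
        )
    node_attrs = node_attrs.sort_values(node_attrs.columns[0]).reset_index(drop=True)
    node_attrs.to_csv(attr_path, sep="\t", index=False)
    return sif_path, attr_path
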