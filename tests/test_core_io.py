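import hashlib

import numpy as np
import pytest

from cernax.core_io import (
    CountMatrix,
    GroupDesign,
    TranscriptRecord,
    read_annotation,
    read_expression,
    read_sequences,
    write_annotation,
    write_expression,
    write_network,
)
from cernax.network_axis import RegulatoryNetwork


def make_design(n=2):
    ids = [f"L{i}" for i in range(n)] + [f"H{i}" for i in range(n)]
    return GroupDesign(tuple(ids), {s: s[0] for s in ids})


class TestReadAnnotation:
    def test_single_transcript_span(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tx\ttranscript\t100\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t100\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        recs = read_annotation(gtf)
        assert len(recs) == 1
        r = recs[0]
        assert (r.start, r.end, r.strand, r.gene_id) == (100, 500, "+", "g1")

    def test_exons_merge_to_transcript_span(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tx\texon\t100\t200\t.\t-\t.\ttranscript_id "t1";\n'
            'chr1\tx\texon\t400\t500\t.\t-\t.\ttranscript_id "t1";\n'
        )
        (r,) = read_annotation(gtf)
        assert (r.start, r.end) == (100, 500)

    def test_empty_file(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text("")
        assert read_annotation(gtf) == []

    def test_malformed_line_names_line_number(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text("chr1\tonly\tthree\n")
        with pytest.raises(ValueError, match="line 1"):
            read_annotation(gtf)

    def test_conflicting_duplicate_raises(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tx\texon\t100\t200\t.\t+\t.\ttranscript_id "t1";\n'
            'chr2\tx\texon\t100\t200\t.\t+\t.\ttranscript_id "t1";\n'
        )
        with pytest.raises(ValueError, match="conflicting"):
            read_annotation(gtf)

    def test_round_trip(self, tmp_path, rng):
        recs = []
        for i in range(30):
            start = int(rng.integers(1, 10_000))
            recs.append(
                TranscriptRecord(
                    f"t{i}", f"g{i}", f"chr{i % 3}", "+" if i % 2 else "-",
                    start, start + int(rng.integers(0, 5000)),
                    biotype=["mRNA", "lncRNA", "unknown"][i % 3],
                )
            )
        path = tmp_path / "rt.gtf"
        write_annotation(recs, path)
        assert read_annotation(path) == recs


class TestReadSequences:
    def test_rna_flag_converts_t_to_u(self, tmp_path):
        fa = tmp_path / "a.fa"
        fa.write_text(">a\nACGT\n")
        assert read_sequences(fa, rna=True) == {"a": "ACGU"}

    def test_wrap_and_case_normalization(self, tmp_path):
        fa = tmp_path / "a.fa"
        fa.write_text(">a\nacg\nt\n")
        assert read_sequences(fa) == {"a": "ACGT"}

    def test_multiple_records_and_id_truncation(self, tmp_path):
        fa = tmp_path / "a.fa"
        fa.write_text(">a some description\nAC\n>b\nGT\n")
        assert read_sequences(fa) == {"a": "AC", "b": "GT"}

    def test_duplicate_id_raises(self, tmp_path):
        fa = tmp_path / "a.fa"
        fa.write_text(">a\nAC\n>a\nGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_sequences(fa)

    def test_bad_character_names_position(self, tmp_path):
        fa = tmp_path / "a.fa"
        fa.write_text(">a\nACXG\n")
        with pytest.raises(ValueError, match="position 3"):
            read_sequences(fa)


class TestReadExpression:
    def test_column_reorder_and_shape(self, tmp_path):
        design = make_design()
        tsv = tmp_path / "e.tsv"
        tsv.write_text(
            "feature\tH1\tL0\tL1\tH0\nf1\t1\t2\t3\t4\nf2\t5\t6\t7\t8\n"
        )
        m = read_expression(tsv, design)
        assert m.sample_ids == list(design.sample_ids)
        assert m.values[0].tolist() == [2, 3, 4, 1]

    def test_extra_column_dropped(self, tmp_path, caplog):
        design = make_design(1)
        tsv = tmp_path / "e.tsv"
        tsv.write_text("feature\tL0\tH0\tZZ\nf1\t1\t2\t3\n")
        m = read_expression(tsv, design)
        assert m.values.shape == (1, 2)

    def test_missing_sample_raises(self, tmp_path):
        design = make_design(1)
        tsv = tmp_path / "e.tsv"
        tsv.write_text("feature\tL0\nf1\t1\n")
        with pytest.raises(ValueError, match="H0"):
            read_expression(tsv, design)

    def test_negative_value_raises(self, tmp_path):
        design = make_design(1)
        tsv = tmp_path / "e.tsv"
        tsv.write_text("feature\tL0\tH0\nf1\t-1\t2\n")
        with pytest.raises(ValueError, match="negative"):
            read_expression(tsv, design)

    def test_values_round_trip_exactly(self, tmp_path, rng):
        design = make_design()
        vals = np.round(rng.uniform(0, 1000, size=(5, 4)), 6)
        m = CountMatrix([f"f{i}" for i in range(5)], list(design.sample_ids), vals)
        path = tmp_path / "rt.tsv"
        write_expression(m, path)
        m2 = read_expression(path, design)
        np.testing.assert_array_equal(m.values, m2.values)


class TestWriteNetwork:
    def _net(self):
        net = RegulatoryNetwork()
        net.add_edge("lncA", "cis", "geneB")
        return net

    def test_sif_content(self, tmp_path):
        sif, _ = write_network(self._net(), None, tmp_path / "n")
        assert sif.read_text() == "lncA cis geneB\n"

    def test_empty_network(self, tmp_path):
        sif, attrs = write_network(RegulatoryNetwork(), None, tmp_path / "n")
        assert sif.read_text() == ""
        assert len(attrs.read_text().splitlines()) == 1  # header only

    def test_byte_identical_across_runs(self, tmp_path):
        net = RegulatoryNetwork()
        for edge in [("c", "cis", "z"), ("a", "cis", "y"), ("b", "cis", "x")]:
            net.add_edge(*edge)
        digests = set()
        for i in range(3):
            sif, attrs = write_network(net, None, tmp_path / f"n{i}")
            digests.add(
                hashlib.md5(sif.read_bytes() + attrs.read_bytes()).hexdigest()
            )
        assert len(digests) == 1

    def test_unknown_node_raises(self, tmp_path):
        net = self._net()
        net.edges.add(("ghost", "cis", "geneB", "none"))
        with pytest.raises(ValueError, match="unknown node"):
            write_network(net, None, tmp_path / "n")
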