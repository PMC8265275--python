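import numpy as np
import pytest

from cernax.cis_target import (
    build_cis_pairs,
    classify_relation,
    expression_correlation,
    trans_candidate,
)
from cernax.core_io import CountMatrix, GroupDesign, TranscriptRecord
from cernax.diffexpr import DEResult
from cernax.mirna_target import duplex_mfe
from oracles import correlation_oracle, relation_oracle


def rec(tid, start, end, strand="+", chrom="chr1", biotype="unknown"):
    return TranscriptRecord(tid, tid, chrom, strand, start, end, biotype=biotype)


class TestClassifyRelation:
    def test_upstream_gap(self):
        relation, d = classify_relation(rec("l", 95_000, 98_000), rec("m", 100_000, 110_000))
        assert (relation, d) == ("upstream", 2000)

    def test_window_boundary_exclusion(self):
        relation, d = classify_relation(rec("l", 60_000, 89_999), rec("m", 100_000, 110_000))
        assert (relation, d) == ("none", 10_001)

    def test_window_boundary_inclusive(self):
        relation, d = classify_relation(rec("l", 60_000, 90_000), rec("m", 100_000, 110_000))
        assert (relation, d) == ("upstream", 10_000)

    def test_strand_reflection(self):
        """5' of a minus-strand gene lies to its right."""
        relation, d = classify_relation(
            rec("l", 110_001, 112_000), rec("m", 100_000, 110_000, strand="-")
        )
        assert (relation, d) == ("upstream", 1)

    def test_overlap_classes(self):
        assert classify_relation(rec("l", 50, 150), rec("m", 100, 200))[0] == "overlap"
        assert (
            classify_relation(rec("l", 50, 150, strand="-"), rec("m", 100, 200))[0]
            == "anti-overlap"
        )

    def test_different_chromosomes(self):
        relation, d = classify_relation(rec("l", 1, 10, chrom="chr2"), rec("m", 1, 10))
        assert relation == "none" and np.isinf(d)

    def test_agrees_with_position_set_oracle(self, rng):
        """Exhaustive agreement over random interval/strand configurations."""
        for _ in range(2000):
            s1, s2 = rng.choice(["+", "-"], size=2)
            a, b = sorted(rng.integers(1, 400, size=2))
            c, d = sorted(rng.integers(1, 400, size=2))
            lnc = rec("l", a, max(b, a), strand=s1)
            mrna = rec("m", c, max(d, c), strand=s2)
            up, down = int(rng.integers(1, 120)), int(rng.integers(1, 250))
            got, _dist = classify_relation(lnc, mrna, up, down)
            assert got == relation_oracle(lnc, mrna, up, down)

    def test_total_and_exclusive(self, rng):
        for _ in range(200):
            a, b = sorted(rng.integers(1, 100, size=2))
            c, d = sorted(rng.integers(1, 100, size=2))
            relation, dist = classify_relation(rec("l", a, max(a, b)), rec("m", c, max(c, d)))
            assert relation in {"upstream", "downstream", "overlap", "anti-overlap", "none"}
            assert dist >= 0


class TestExpressionCorrelation:
    def test_exact_linear(self):
        p, s = expression_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert p == pytest.approx(1.0)
        assert s == pytest.approx(1.0)

    def test_hand_computed(self):
        p, s = expression_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert p == pytest.approx(0.8)
        assert s == pytest.approx(0.8)  # 1 - 6*2/(4*15)

    def test_antitone(self):
        p, s = expression_correlation([1, 2, 3], [3, 2, 1])
        assert p == pytest.approx(-1.0)
        assert s == pytest.approx(-1.0)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="constant"):
            expression_correlation([1, 1, 1], [1, 2, 3])

    def test_agrees_with_two_pass_reference(self, rng):
        for _ in range(30):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            p, s = expression_correlation(x, y)
            p2, s2 = correlation_oracle(x, y)
            assert p == pytest.approx(p2, abs=1e-12)
            assert s == pytest.approx(s2, abs=1e-12)


class TestTransCandidate:
    def test_perfect_gc_duplex_is_trans(self, rng):
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        mrna = "".join(rng.choice(["G", "C", "A", "U"], size=200, p=[0.4, 0.4, 0.1, 0.1]))
        window = mrna[80:120]
        lnc = "A" * 60 + "".join(comp[b] for b in reversed(window)) + "A" * 60
        mfe, is_trans = trans_candidate(lnc, mrna)
        assert is_trans and mfe < -30

    def test_poly_a_never_trans(self):
        mfe, is_trans = trans_candidate("A" * 100, "A" * 100)
        assert (mfe, is_trans) == (0.0, False)

    def test_stride1_oracle_is_lower_bound(self, rng):
        lnc = "".join(rng.choice(list("ACGU"), size=90))
        mrna = "".join(rng.choice(list("ACGU"), size=90))
        coarse, _ = trans_candidate(lnc, mrna, window=40, step=20)
        fine = min(
            duplex_mfe(lnc[i : i + 40], mrna[j : j + 40])
            for i in range(0, 51, 5)
            for j in range(0, 51, 5)
        )
        assert fine <= coarse

    def test_short_sequence_raises(self):
        with pytest.raises(ValueError):
            trans_candidate("ACGU", "ACGU" * 20)


class TestBuildCisPairs:
    def _setup(self, corr_high=True):
        rng = np.random.default_rng(5)
        design = GroupDesign(
            ("L1", "L2", "L3", "H1", "H2", "H3"),
            {s: s[0] for s in ("L1", "L2", "L3", "H1", "H2", "H3")},
        )
        annotation = [
            rec("m1", 100_000, 102_000, biotype="mRNA"),
            rec("l1", 95_000, 96_000, biotype="lncRNA"),
        ]
        base = rng.uniform(50, 150, size=6)
        if corr_high:
            lnc_vals = base * rng.lognormal(0, 0.05, size=6)
        else:
            lnc_vals = rng.uniform(50, 150, size=6)
        expr = CountMatrix(["m1", "l1"], list(design.sample_ids),
                           np.vstack([base, lnc_vals]), unit="FPKM")
        de_lnc = [DEResult("l1", 1, 4, 2.0, 1e-9, q=1e-6, direction="Up", significant=True)]
        de_mrna = [DEResult("m1", 1, 4, 2.0, 1e-9, q=1e-6, direction="Up", significant=True)]
        return annotation, expr, de_lnc, de_mrna

    def test_planted_neighbor_pair_recovered(self):
        annotation, expr, de_lnc, de_mrna = self._setup(corr_high=True)
        pairs = build_cis_pairs(annotation, expr, de_lnc, de_mrna)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.lnc_id, p.mrna_id, p.relation) == ("l1", "m1", "upstream")
        assert p.mrna_is_de

    def test_low_correlation_gated_out(self):
        annotation, expr, de_lnc, de_mrna = self._setup(corr_high=False)
        assert build_cis_pairs(annotation, expr, de_lnc, de_mrna) == []

    def test_planted_pairs_recovered_from_simulation(self, sim_data):
        from cernax.pipeline import run_from_data

        d = sim_data
        r = run_from_data(d.annotation, d.sequences, d.mirna_sequences,
                          d.counts, d.mirna_counts, d.design)
        found = {(p.lnc_id, p.mrna_id) for p in r.cis_pairs}
        assert d.truth.cis_pairs <= found
        # near-window and low-correlation decoys never form pairs
        assert not (d.truth.near_window_decoys & found)
        assert not (d.truth.low_corr_decoys & found)
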