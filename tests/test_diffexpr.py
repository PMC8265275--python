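import math

import numpy as np
import pytest
from scipy import stats

from cernax import datasets
from cernax.core_io import CountMatrix, GroupDesign
from cernax.diffexpr import (
    DEResult,
    ScaleConstant,
    bh_adjust,
    call_de,
    de_table,
    de_test,
    fit_scale_from_reference,
    fpkm_bins,
    log2_fold_change,
    normalize,
)
from oracles import bh_oracle


def make_design(n=2):
    ids = [f"L{i}" for i in range(n)] + [f"H{i}" for i in range(n)]
    return GroupDesign(tuple(ids), {s: s[0] for s in ids})


class TestNormalize:
    def test_proportional_libraries_equalize(self):
        design = make_design(1)
        m = CountMatrix(["f1", "f2"], list(design.sample_ids),
                        np.array([[10.0, 20.0], [999_990.0, 1_999_980.0]]))
        normed, factors = normalize(m, design)
        assert normed.values[0, 0] == pytest.approx(normed.values[0, 1])
        assert factors[1] == pytest.approx(factors[0] / 2)

    def test_columns_sum_to_million(self, rng):
        design = make_design()
        m = CountMatrix([f"f{i}" for i in range(5)], list(design.sample_ids),
                        rng.integers(1, 1000, size=(5, 4)).astype(float))
        normed, _ = normalize(m, design)
        np.testing.assert_allclose(normed.values.sum(axis=0), 1e6)

    def test_zero_total_column_raises(self):
        design = make_design(1)
        m = CountMatrix(["f1"], list(design.sample_ids), np.array([[0.0, 5.0]]))
        with pytest.raises(ValueError, match="zero-total"):
            normalize(m, design)


class TestLog2FoldChange:
    def test_identity(self):
        assert log2_fold_change(123.4, 123.4, ScaleConstant(1.0)) == 0.0

    def test_published_small_rna_row(self):
        """Fitted small-RNA library constant reproduces the printed value."""
        c = fit_scale_from_reference(
            datasets.rows_for_fit(datasets.TOP_DES_TABLE, "miR-92a_1")
        )
        assert log2_fold_change(35074, 7418, c) == pytest.approx(-1.78953, abs=0.01)

    def test_published_lncrna_row(self):
        c = fit_scale_from_reference(
            datasets.rows_for_fit(datasets.TOP_DEL_TABLE, "LTCONS_00020831")
        )
        assert log2_fold_change(79374.24, 168343.7, c) == pytest.approx(1.213923, abs=0.01)

    def test_nonpositive_mean_raises(self):
        with pytest.raises(ValueError):
            log2_fold_change(0.0, 5.0)


class TestFitScale:
    def test_identity_calibration(self):
        rows = [(10.0, 40.0, 2.0), (100.0, 50.0, -1.0)]
        assert fit_scale_from_reference(rows).c == pytest.approx(1.0)

    def test_fitted_constants_match_closed_form(self):
        """Median implied constant of each published table."""
        for table, expected in [
            (datasets.TOP_DEL_TABLE, 1.094),
            (datasets.TOP_DES_TABLE, 1.368),
        ]:
            rows = [(L, H, lfc) for _f, L, H, lfc in table]
            implied = sorted(2.0**lfc * L / H for L, H, lfc in rows)
            k = len(implied)
            median = (implied[k // 2] if k % 2 else
                      (implied[k // 2 - 1] + implied[k // 2]) / 2)
            c = fit_scale_from_reference(rows).c
            assert c == pytest.approx(median, rel=1e-12)
            assert c == pytest.approx(expected, abs=0.002)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            fit_scale_from_reference([])


class TestDeTest:
    def test_null_center(self):
        design = make_design()
        p = de_test(np.array([25, 25, 25, 25]), design, np.array([1e6] * 4))
        assert p == pytest.approx(1.0)

    def test_closed_form_z(self):
        """400 vs 100 with equal totals matches the hand-computed z tail."""
        design = make_design(1)
        p = de_test(np.array([100, 400]), design, np.array([1e6, 1e6]))
        z = (0.8 - 0.5) / math.sqrt(0.25 / 500)
        assert p == pytest.approx(2 * stats.norm.sf(z), rel=1e-12)

    def test_more_evidence_same_proportion(self):
        design = make_design(1)
        p1 = de_test(np.array([100, 200]), design, np.array([1e6, 1e6]))
        p2 = de_test(np.array([200, 400]), design, np.array([2e6, 2e6]))
        assert p2 <= p1

    def test_all_zero_counts(self):
        design = make_design(1)
        assert de_test(np.array([0, 0]), design, np.array([1e6, 1e6])) == 1.0

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            de_test(np.array([-1, 5]), make_design(1))


class TestBhAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_adjust([0.001, 0.01, 0.03]), [0.003, 0.015, 0.03]
        )

    def test_single_value_identity(self):
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])

    def test_matches_naive_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_never_below_raw_p(self, rng):
        p = rng.uniform(0, 1, size=100)
        assert np.all(bh_adjust(p) >= p)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDe:
    @pytest.mark.parametrize(
        "lfc, q, sig, direction",
        [
            (1.0, 0.001, True, "Up"),       # both boundaries inclusive
            (0.99, 1e-9, False, "none"),
            (-3.0, 0.0011, False, "none"),
            (-1.0, 0.001, True, "Down"),
        ],
    )
    def test_gate(self, lfc, q, sig, direction):
        (r,) = call_de([DEResult("f", 1, 1, lfc, 0.0, q=q)])
        assert (r.significant, r.direction) == (sig, direction)

    def test_threshold_monotone(self, rng):
        results = [
            DEResult(f"f{i}", 1, 1, float(rng.normal(0, 2)), 0.0,
                     q=float(rng.uniform(0, 0.01)))
            for i in range(50)
        ]
        strict = {r.feature_id for r in call_de(results, 2.0, 0.001) if r.significant}
        loose = {r.feature_id for r in call_de(results, 2.0, 0.005) if r.significant}
        assert strict <= loose


class TestFpkmBins:
    def test_boundary_placement(self):
        design = make_design(1)
        m = CountMatrix(["a", "b", "c", "d"], ["L0", "H0"],
                        np.array([[0.5] * 2, [1.0] * 2, [5.0] * 2, [10.0] * 2]),
                        unit="FPKM")
        assert fpkm_bins(m)["L0"] == (2, 1, 1)

    def test_all_zero(self):
        m = CountMatrix(["a", "b"], ["s"], np.zeros((2, 1)), unit="FPKM")
        assert fpkm_bins(m)["s"] == (2, 0, 0)

    def test_partition_property(self, rng):
        m = CountMatrix([f"f{i}" for i in range(30)], ["s1", "s2"],
                        rng.uniform(0, 20, size=(30, 2)), unit="FPKM")
        for counts in fpkm_bins(m).values():
            assert sum(counts) == 30

    def test_wrong_unit_raises(self):
        m = CountMatrix(["a"], ["s"], np.ones((1, 1)), unit="count")
        with pytest.raises(ValueError):
            fpkm_bins(m)


class TestDeTable:
    def test_q_at_least_p_and_planted_shift_called(self, rng):
        design = make_design(3)
        base = rng.uniform(100, 1000, size=20)
        vals = rng.poisson(base[:, None], size=(20, 6)).astype(float)
        vals[0, 3:] *= 8  # strong planted H shift
        m = CountMatrix([f"f{i}" for i in range(20)], list(design.sample_ids), vals)
        res = de_table(m, design)
        assert all(r.q >= r.p for r in res)
        assert res[0].significant and res[0].direction == "Up"
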