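import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cnvassay as ca

LOG10_2 = np.log10(2)


def plate(rows):
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "cq", "role"])


def simple_plate(cq_target_by_sample, ref_cq=20.0):
    rows = []
    for sample, cq in cq_target_by_sample.items():
        rows.append((sample, "GENE", 0, cq, "target"))
        rows.append((sample, "HPRT1", 0, ref_cq, "reference"))
    return plate(rows)


class TestDdcq:
    def test_calibrator_fold_change_is_one(self):
        res = ca.ddcq_fold_change(simple_plate({"cal": 25.0, "s": 26.0}))
        by = {e.sample: e for e in res}
        assert by["cal"].fold_change == pytest.approx(1.0)

    def test_three_cycle_shift_is_eighth(self):
        res = ca.ddcq_fold_change(simple_plate({"cal": 25.0, "ko": 28.0}))
        by = {e.sample: e for e in res}
        assert by["ko"].delta_delta_cq == pytest.approx(3.0)
        assert by["ko"].fold_change == pytest.approx(0.125)

    def test_two_reference_genes_aggregate_as_mean_cq(self):
        rows = [
            ("cal", "GENE", 0, 25.0, "target"),
            ("cal", "HPRT1", 0, 20.0, "reference"),
            ("cal", "COPE", 0, 22.0, "reference"),
            ("ko", "GENE", 0, 27.0, "target"),
            ("ko", "HPRT1", 0, 21.0, "reference"),
            ("ko", "COPE", 0, 23.0, "reference"),
        ]
        res = ca.ddcq_fold_change(plate(rows))
        by = {e.sample: e for e in res}
        # reference aggregate rose by 1 cycle, target by 2: net ddcq = 1
        assert by["ko"].fold_change == pytest.approx(0.5)

    @given(st.floats(min_value=-5, max_value=5))
    @settings(deadline=None, derandomize=True)
    def test_plate_shift_invariance(self, shift):
        base = simple_plate({"cal": 25.0, "ko": 28.7})
        shifted = base.assign(cq=base["cq"] + shift)
        a = {e.sample: e.fold_change for e in ca.ddcq_fold_change(base)}
        b = {e.sample: e.fold_change for e in ca.ddcq_fold_change(shifted)}
        assert a["ko"] == pytest.approx(b["ko"], rel=1e-12)

    def test_replicate_sd_propagates_to_interval(self):
        rows = [("cal", "GENE", i, 25.0, "target") for i in range(4)]
        rows += [("cal", "HPRT1", i, 20.0, "reference") for i in range(4)]
        rows += [("ko", "GENE", i, cq, "target") for i, cq in enumerate([27.8, 28.2, 28.1, 27.9])]
        rows += [("ko", "HPRT1", i, 20.0, "reference") for i in range(4)]
        (ko,) = [e for e in ca.ddcq_fold_change(plate(rows)) if e.sample == "ko"]
        assert ko.fold_change_low < ko.fold_change < ko.fold_change_high
        assert ko.fold_change_high / ko.fold_change == pytest.approx(2 ** ko.cq_sd)

    def test_missing_reference_rejected(self):
        rows = [("cal", "GENE", 0, 25.0, "target"),
                ("cal", "HPRT1", 0, 20.0, "reference"),
                ("ko", "GENE", 0, 28.0, "target")]
        with pytest.raises(ValueError, match="reference"):
            ca.ddcq_fold_change(plate(rows))

    def test_non_positive_cq_rejected(self):
        with pytest.raises(ValueError):
            ca.ddcq_fold_change(simple_plate({"cal": -1.0}))


class TestFoldReduction:
    @pytest.mark.parametrize("fraction,expected", [
        (0.0638, 15.7), (0.0878, 11.4), (1.0, 1.0),
    ])
    def test_reported_folds(self, fraction, expected):
        assert ca.fold_reduction(fraction) == expected

    def test_reciprocal_identity(self):
        fc = 0.31
        assert ca.fold_reduction(fc, decimals=12) * fc == pytest.approx(1.0)

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.2])
    def test_not_a_reduction_rejected(self, fraction):
        with pytest.raises(ValueError):
            ca.fold_reduction(fraction)


def perfect_curve(intercept=20.0, slope=-1 / LOG10_2):
    q = np.array([100.0, 20.0, 4.0, 0.8, 0.16])  # 5-point 5-fold series
    cq = intercept + slope * np.log10(q)
    return q, cq


class TestStandardCurve:
    def test_full_efficiency_slope(self):
        q, cq = perfect_curve()
        curve = ca.fit_standard_curve(q, cq)
        assert curve.slope == pytest.approx(-3.3219, abs=1e-4)
        assert curve.efficiency == pytest.approx(1.00, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_efficiency_formula_at_slope_minus_3_6(self):
        q = np.array([100.0, 20.0, 4.0, 0.8, 0.16])
        cq = 20.0 + -3.6 * np.log10(q)
        curve = ca.fit_standard_curve(q, cq)
        assert curve.efficiency == pytest.approx(0.8957, abs=2e-4)

    def test_round_trip_exact_at_zero_noise(self):
        q, cq = perfect_curve()
        curve = ca.fit_standard_curve(q, cq)
        for truth in (0.5, 3.0, 80.0):
            back = ca.absolute_quantity(curve, curve.cq_of(truth))
            assert back.quantity == pytest.approx(truth, rel=1e-9)
            assert not back.extrapolated

    def test_cq_at_intercept_is_unit_quantity(self):
        q, cq = perfect_curve(intercept=23.0)
        curve = ca.fit_standard_curve(q, cq)
        assert ca.absolute_quantity(curve, 23.0).quantity == pytest.approx(1.0)

    def test_out_of_range_flagged_extrapolated(self):
        q, cq = perfect_curve()
        curve = ca.fit_standard_curve(q, cq)
        low_cq = curve.cq_of(0.01)  # below the 0.16 end of the series
        assert ca.absolute_quantity(curve, low_cq).extrapolated

    def test_noisy_quantification_median_error_below_20pct(self):
        rng = np.random.default_rng(5)
        q, cq = perfect_curve()
        curve = ca.fit_standard_curve(q, cq)
        truths = rng.uniform(0.2, 90.0, size=1000)
        noisy_cq = curve.cq_of(truths) + rng.normal(0, 0.2, size=1000)
        est = np.array([ca.absolute_quantity(curve, c).quantity for c in noisy_cq])
        rel_err = np.abs(est - truths) / truths
        assert np.median(rel_err) < 0.20

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ca.fit_standard_curve([1.0, 1.0, 1.0], [20.0, 20.0, 20.0])
        with pytest.raises(ValueError):
            ca.fit_standard_curve([10.0, 1.0, -1.0], [20.0, 23.3, 26.6])


class TestCountEndpoints:
    @pytest.mark.parametrize("pos,total,expected", [
        (2, 4, 50.0), (1, 9, 11.1), (0, 5, 0.0), (8, 8, 100.0),
    ])
    def test_penetrance(self, pos, total, expected):
        assert ca.penetrance(pos, total) == expected

    @pytest.mark.parametrize("colonies,plated,expected", [
        (128, 2000, 6.4), (0, 500, 0.0), (100, 100, 100.0),
    ])
    def test_clonogenic(self, colonies, plated, expected):
        assert ca.clonogenic_ability(colonies, plated) == expected

    @given(st.integers(min_value=0, max_value=100), st.integers(min_value=1, max_value=100),
           st.integers(min_value=2, max_value=20))
    @settings(deadline=None, derandomize=True)
    def test_scale_free(self, k, n, factor):
        k = min(k, n)
        assert ca.penetrance(k, n) == ca.penetrance(k * factor, n * factor)
        assert ca.clonogenic_ability(k, n) == ca.clonogenic_ability(k * factor, n * factor)

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError):
            ca.penetrance(1, 0)
        with pytest.raises(ValueError):
            ca.penetrance(5, 4)
        with pytest.raises(ValueError):
            ca.clonogenic_ability(1, 0)


class TestKaryotypeSummary:
    def test_published_categories_total(self):
        summary = ca.karyotype_summary(
            {"dicentric": 61.43, "acentric": 7.85, "gaps": 6.14, "fragments": 9.22})
        assert summary.total_aberrant_percent == 84.64

    def test_empty_map_is_zero(self):
        assert ca.karyotype_summary({}).total_aberrant_percent == 0.0

    def test_over_100_rejected(self):
        with pytest.raises(ValueError):
            ca.karyotype_summary({"a": 50.0, "b": 60.0})
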