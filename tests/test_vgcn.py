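"""Standard-curve qPCR quantification, Grubbs screen and OLS regression."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from aavquant import (
    GENOMES_PER_10NG,
    PERFECT_SLOPE,
    curve_from_table,
    efficiency_from_slope,
    fit_standard_curve,
    grubbs_test,
    linear_regression,
    quantify_samples,
    quantify_vgcn,
    simulate_cq,
)
import pandas as pd

DILUTIONS = [1e8, 1e7, 1e6, 1e5, 1e4]  # 10-fold plasmid series


def perfect_cq(copies, intercept=37.0):
    return [intercept + PERFECT_SLOPE * math.log10(c) for c in copies]


class TestStandardCurve:
    def test_perfect_doubling_gives_100_percent_efficiency(self):
        # Cq spaced +log2(10) per 10-fold dilution <=> doubling every cycle
        curve = fit_standard_curve(DILUTIONS, perfect_cq(DILUTIONS))
        assert curve.slope == pytest.approx(PERFECT_SLOPE, abs=1e-9)
        assert curve.efficiency_pct == pytest.approx(100.0, abs=1e-6)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_five_point_dilution_series_uses_all_points(self):
        curve = fit_standard_curve(DILUTIONS, perfect_cq(DILUTIONS))
        assert curve.n_points == 5

    def test_noisy_fit_recovers_generating_parameters(self):
        # simulation with known slope/intercept; estimates within 3 se
        slope_true, intercept_true = -3.45, 36.2
        cq = simulate_cq(DILUTIONS, slope=slope_true, intercept=intercept_true, sd=0.1, rng=7)
        curve = fit_standard_curve(DILUTIONS, [list(row) for row in cq])
        logs = np.log10(DILUTIONS)
        fit = sps.linregress(logs, cq.mean(axis=1))
        assert abs(curve.slope - slope_true) <= 3 * fit.stderr
        assert abs(curve.intercept - intercept_true) <= 3 * fit.intercept_stderr

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve([1e8, 1e6], perfect_cq([1e8, 1e6]))

    def test_narrow_range_rejected(self):
        pts = [1e6, 2e6, 4e6]
        with pytest.raises(ValueError):
            fit_standard_curve(pts, perfect_cq(pts))

    def test_positive_slope_flagged_not_raised(self):
        # Cq rising with template amount is chemically impossible: the fit
        # succeeds but carries a warning and no efficiency
        curve = fit_standard_curve([1e4, 1e5, 1e6, 1e7, 1e8], [20.0, 25.0, 30.0, 35.0, 40.0])
        assert curve.slope > 0
        assert curve.warning is not None
        assert math.isnan(curve.efficiency_pct)
        with pytest.raises(ValueError):
            quantify_vgcn([30.0], curve)

    def test_efficiency_monotone_in_slope(self):
        slopes = [-3.6, -3.45, PERFECT_SLOPE, -3.1]
        effs = [efficiency_from_slope(s) for s in slopes]
        assert effs == sorted(effs)
        assert effs[2] == pytest.approx(100.0, abs=1e-6)


class TestQuantifyVgcn:
    CURVE = fit_standard_curve(DILUTIONS, perfect_cq(DILUTIONS))

    def test_cq_at_intercept_is_one_copy(self):
        res = quantify_vgcn([self.CURVE.intercept], self.CURVE)
        assert res.vgcn_per_10ng == pytest.approx(1.0, rel=1e-9)

    def test_round_trip_copies_to_cq_to_copies(self):
        for copies in (1e4, 3.7e5, 1e8):
            cq = self.CURVE.cq_from_copies(copies)
            assert self.CURVE.copies_from_cq(cq) == pytest.approx(copies, rel=1e-9)

    def test_simulated_sample_recovered_within_replicate_noise(self):
        true_copies = 2.5e6
        cq = simulate_cq(true_copies, sd=0.05, rng=3)[0]
        res = quantify_vgcn(list(cq), self.CURVE)
        # 3 replicates at sd 0.05 cycles: ~3.5% sd on copies
        assert res.vgcn_per_10ng == pytest.approx(true_copies, rel=0.1)
        assert res.vgcn_per_genome == pytest.approx(res.vgcn_per_10ng / GENOMES_PER_10NG)

    def test_round_trip_bias_below_2_percent(self):
        # quantify(simulate) over the assay's full dynamic range
        rng = np.random.default_rng(12)
        for copies in (1e4, 1e5, 1e6, 1e7, 1e8):
            est = []
            for _ in range(40):
                cq = simulate_cq(copies, sd=0.1, rng=rng)[0]
                est.append(quantify_vgcn(list(cq), self.CURVE).vgcn_per_10ng)
            assert abs(np.mean(est) - copies) / copies < 0.02

    def test_no_signal_cq_reports_zero_with_flag(self):
        res = quantify_vgcn([41.2, 40.8, 42.0], self.CURVE)
        assert res.no_signal is True
        assert res.vgcn_per_10ng == 0.0

    def test_table_workflow(self, tmp_path):
        rows = []
        for copies in DILUTIONS:
            for rep, cq in enumerate(perfect_cq([copies] * 3)):
                rows.append(("standard", copies, rep, cq))
        for rep in range(3):
            rows.append(("blood_1", "sample", rep, self.CURVE.cq_from_copies(1.02e6)))
        df = pd.DataFrame(rows, columns=["sample_id", "dilution_or_sample", "replicate", "cq"])
        curve = curve_from_table(df)
        results = quantify_samples(df, curve)
        assert results[0].sample_id == "blood_1"
        assert results[0].vgcn_per_10ng == pytest.approx(1.02e6, rel=1e-6)


class TestGrubbs:
    def test_detects_obvious_outlier(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 100.0]
        idx, g, crit = grubbs_test(values, alpha=0.05)
        assert idx == 5
        # closed-form oracle for G and the critical value
        x = np.array(values)
        g_expected = np.abs(x - x.mean()).max() / x.std(ddof=1)
        n = len(x)
        t = sps.t.ppf(1 - 0.05 / (2 * n), n - 2)
        crit_expected = (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))
        assert g == pytest.approx(g_expected)
        assert crit == pytest.approx(crit_expected)
        assert g > crit

    def test_symmetric_data_has_no_outlier(self):
        idx, g, crit = grubbs_test([-1.0, 0.0, 1.0], alpha=0.05)
        assert idx is None

    def test_typical_measurement_sets_pass_clean(self):
        # replicate-style data with modest spread: the no-outlier path
        rng = np.random.default_rng(0)
        for _ in range(10):
            values = rng.normal(1.02e6, 0.14e6, size=6)
            idx, _, _ = grubbs_test(list(values), alpha=0.05)
            assert idx is None

    def test_input_validation(self):
        with pytest.raises(ValueError):
            grubbs_test([1.0, 2.0], alpha=0.05)
        with pytest.raises(ValueError):
            grubbs_test([3.0, 3.0, 3.0], alpha=0.05)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.01, 1e6),
        shift=st.floats(-1e6, 1e6),
    )
    def test_invariant_to_affine_rescaling(self, scale, shift):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 100.0]
        rescaled = [scale * v + shift for v in values]
        idx_a, g_a, crit_a = grubbs_test(values)
        idx_b, g_b, crit_b = grubbs_test(rescaled)
        assert idx_a == idx_b
        assert g_a == pytest.approx(g_b, rel=1e-6)
        assert crit_a == crit_b


class TestLinearRegression:
    def test_exact_line(self):
        x = [0.0, 1.0, 2.0, 3.0]
        y = [2 * v + 1 for v in x]
        slope, intercept, r2, _ = linear_regression(x, y)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_uncorrelated_data_rarely_significant(self):
        # n=8 independent draws: slope p-value > 0.05 in >= 90% of seeds
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=8), rng.normal(size=8)
            *_, p = linear_regression(list(x), list(y))
            hits += p > 0.05
        assert hits >= 90

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=15)
        y = 0.7 * x + rng.normal(scale=0.3, size=15)
        slope, intercept, r2, p = linear_regression(list(x), list(y))
        # closed-form oracle: normal equations and the slope t test
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope_exp = sxy / sxx
        intercept_exp = y.mean() - slope_exp * x.mean()
        resid = y - (slope_exp * x + intercept_exp)
        s2 = (resid**2).sum() / (len(x) - 2)
        t_stat = slope_exp / math.sqrt(s2 / sxx)
        p_exp = 2 * sps.t.sf(abs(t_stat), len(x) - 2)
        assert slope == pytest.approx(slope_exp)
        assert intercept == pytest.approx(intercept_exp)
        assert p == pytest.approx(p_exp)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
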