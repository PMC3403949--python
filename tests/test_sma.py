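import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allomass.core_data import BivariateLogSample
from allomass.sma import (
    adjust_fdr,
    classify_similarity,
    compare_intercepts,
    compare_slopes_lrt,
    fit_sma,
    pairwise_comparison_matrix,
    test_slope_value as slope_value_test,
)


def sample(x, y, name="s"):
    x = np.asarray(x, dtype=float)
    return BivariateLogSample("x", "y", x, np.asarray(y, dtype=float),
                              [f"{name}{i}" for i in range(len(x))])


def random_sample(rng, n=None):
    n = n or rng.integers(5, 60)
    x = rng.uniform(0, 3, n)
    y = rng.uniform(1, 4) * x + rng.normal(0, rng.uniform(0.01, 0.5), n)
    return sample(x, y)


class TestFitSMA:
    def test_exact_line(self):
        f = fit_sma(sample([1, 2, 3], [2, 5, 8]))
        assert f.m == pytest.approx(3.0)
        assert f.b == pytest.approx(-1.0)
        assert f.R2 == pytest.approx(1.0)

    def test_three_point_example(self):
        # moments by hand: var_x=1, var_y=0.91, cov=0.95
        f = fit_sma(sample([1, 2, 3], [0.5, 1.6, 2.4]))
        assert f.m == pytest.approx(0.95394, abs=1e-5)
        assert f.b == pytest.approx(-0.40788, abs=1e-5)
        assert f.R2 == pytest.approx(0.99176, abs=1e-5)

    def test_slope_is_sd_ratio_and_ci_brackets(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            s = random_sample(rng)
            f = fit_sma(s)
            sd_ratio = np.std(s.y, ddof=1) / np.std(s.x, ddof=1)
            assert abs(f.m) == pytest.approx(sd_ratio, rel=1e-12)
            assert f.ci_lower <= f.m <= f.ci_upper
            assert math.copysign(1, f.m) == math.copysign(1, f.r)
            assert f.b == pytest.approx(f.mean_y - f.m * f.mean_x, rel=1e-12)

    def test_axis_swap_inverts_slope(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = random_sample(rng)
            assert fit_sma(s.swapped()).m == pytest.approx(1 / fit_sma(s).m, rel=1e-10)

    def test_scale_equivariance(self):
        # multiplying raw x by c shifts log10 x by log10(c): slope fixed,
        # intercept shifted by -m*log10(c)
        rng = np.random.default_rng(3)
        s = random_sample(rng, 30)
        c = 7.3
        shifted = sample(s.x + math.log10(c), s.y)
        f0, f1 = fit_sma(s), fit_sma(shifted)
        assert f1.m == pytest.approx(f0.m, rel=1e-12)
        assert f1.b == pytest.approx(f0.b - f0.m * math.log10(c), rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_sma(sample([1, 1, 1], [1, 2, 3]))

    def test_zero_correlation_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_sma(sample([-1, 0, 1, 0], [0, 1, 0, -1]))


class TestSlopeTest:
    def test_fitted_slope_gives_p_one(self):
        s = sample([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.9])
        f = fit_sma(s)
        res = slope_value_test(f, s, f.m)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_three_point_example_against_one(self):
        s = sample([1, 2, 3], [0.5, 1.6, 2.4])
        res = slope_value_test(fit_sma(s), s, 1.0)
        assert res.statistic == pytest.approx(-0.5197, abs=1e-4)
        assert res.df == 1
        assert res.p == pytest.approx(0.695, abs=1e-3)

    def test_collinear_sample(self):
        s = sample([1, 2, 3], [2, 4, 6])
        f = fit_sma(s)
        assert slope_value_test(f, s, 2.0).p == 1.0
        with pytest.raises(ValueError, match="collinear"):
            slope_value_test(f, s, 3.0)


class TestSimilarity:
    def test_wide_ci_consistent_with_all_models(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 12)
        y = 2.7 * x + rng.normal(0, 0.35, 12)
        s = sample(x, y)
        f = fit_sma(s)
        v = classify_similarity(f, s, "mass~circumference")
        assert v.consistent_models == {"G", "E", "S"}
        assert v.code == "G, E, S"

    def test_slope_between_elastic_and_geometric(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 3, 400)
        y = 2.85 * x + rng.normal(0, 0.05, 400)
        s = sample(x, y)
        v = classify_similarity(fit_sma(s), s, "mass~circumference")
        assert v.code == "< G, > E"

    def test_slope_below_all_models_is_zero_code(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 3, 400)
        y = 2.0 * x + rng.normal(0, 0.05, 400)
        s = sample(x, y)
        v = classify_similarity(fit_sma(s), s, "mass~circumference")
        assert v.code == "0" and not v.consistent_models

    def test_unregistered_relation(self):
        s = sample([1, 2, 3], [0.5, 1.6, 2.4])
        assert classify_similarity(fit_sma(s), s, None).code == "-"


class TestCommonSlopeLRT:
    def test_identical_groups_statistic_zero(self):
        rng = np.random.default_rng(7)
        s = random_sample(rng, 40)
        slope, stat, df, p = compare_slopes_lrt([s, s])
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-6)
        assert slope == pytest.approx(fit_sma(s).m, rel=1e-6)
        assert df == 1

    def test_distinct_slopes_detected(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 3, 100)
        g1 = sample(x, 2.5 * x + rng.normal(0, 0.05, 100))
        g2 = sample(x, 3.5 * x + rng.normal(0, 0.05, 100))
        _, stat, _, p = compare_slopes_lrt([g1, g2])
        assert p < 1e-6

    def test_three_group_df(self):
        rng = np.random.default_rng(9)
        groups = [random_sample(rng, 30) for _ in range(3)]
        _, _, df, _ = compare_slopes_lrt(groups)
        assert df == 2


class TestInterceptComparison:
    def test_identical_fits(self):
        rng = np.random.default_rng(10)
        f = fit_sma(random_sample(rng, 50))
        t, df, p = compare_intercepts(f, f, 0.0)
        assert t == 0.0 and p == 1.0
        assert df == 2 * f.n - 4

    def test_offset_elevations_detected(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(1, 3, 50)
        a = fit_sma(sample(x, 2.7 * x + 0.0 + rng.normal(0, 0.05, 50)))
        b = fit_sma(sample(x, 2.7 * x + 1.0 + rng.normal(0, 0.05, 50)))
        _, _, p0 = compare_intercepts(a, b, 0.0)
        _, _, pm = compare_intercepts(a, b, float(np.min(x)))
        assert p0 < 1e-3 and pm < 1e-3

    def test_shifted_evaluation_can_remove_difference(self):
        # same line sampled over different ranges: intercept at 0 is an
        # extrapolation artefact, elevations at the shared minimum agree
        rng = np.random.default_rng(12)
        x1, x2 = rng.uniform(1, 2, 80), rng.uniform(2, 3, 80)
        a = fit_sma(sample(x1, 2.7 * x1 + rng.normal(0, 0.08, 80)))
        b = fit_sma(sample(x2, 2.7 * x2 + rng.normal(0, 0.08, 80)))
        _, _, pmin = compare_intercepts(a, b, 1.0)
        assert pmin > 0.01


class TestFDR:
    @pytest.mark.parametrize("p_in, expected", [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.04, 0.04], [0.015, 0.04, 0.04]),
    ])
    def test_step_up_examples(self, p_in, expected):
        np.testing.assert_allclose(adjust_fdr(p_in), expected, atol=1e-12)

    def test_adjusted_at_least_raw_and_order_preserved(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0, 1, 20)
        adj = adjust_fdr(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        # largest p maps to itself after capping
        assert adj[np.argmax(p)] == pytest.approx(p.max())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_matches_min_over_tail_definition(self, p):
        # independent oracle: adj_(i) = min_{j >= i} p_(j) * m / (j+1), capped
        p = np.array(p)
        order = np.argsort(p, kind="stable")
        m = len(p)
        adj_sorted = [
            min(min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0)
            for i in range(m)
        ]
        oracle = np.empty(m)
        oracle[order] = adj_sorted
        np.testing.assert_allclose(adjust_fdr(p), oracle, atol=1e-12)


class TestPairwiseMatrix:
    def test_small_groups_excluded_with_warning(self):
        rng = np.random.default_rng(14)
        groups = {"big": random_sample(rng, 40), "small": random_sample(rng, 5)}
        with pytest.warns(UserWarning, match="excluded"):
            cells = pairwise_comparison_matrix(groups)
        assert cells == []

    def test_cells_carry_fdr_at_least_raw(self):
        rng = np.random.default_rng(15)
        groups = {f"g{i}": random_sample(rng, 40) for i in range(4)}
        cells = pairwise_comparison_matrix(groups, analysis="test")
        assert len(cells) == 6
        for c in cells:
            assert c.lrt_p_fdr >= c.lrt_p - 1e-15
            assert c.p_intercept_fdr >= c.p_intercept - 1e-15
            assert c.p_shifted_fdr >= c.p_shifted - 1e-15

    def test_null_population_rarely_significant(self):
        # groups drawn from one population: no FDR-significant slope cells
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            groups = {}
            for g in range(4):
                x = rng.uniform(1, 3, 40)
                groups[f"g{g}"] = sample(x, 2.7 * x - 1 + rng.normal(0, 0.1, 40))
            cells = pairwise_comparison_matrix(groups)
            hits += any(c.lrt_p_fdr < 0.05 for c in cells)
        assert hits <= 2
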