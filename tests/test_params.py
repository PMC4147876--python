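"""Parameter model: triangular law, interpolation rules, cost schedule."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, strategies as st

from overdent.params import (
    CostSchedule,
    TriangularDist,
    interpolate_failure_table,
    interpolate_satisfaction,
    labor_cost_at_factor,
    sample_triangular,
    triangular_mean,
    triangular_ppf,
)
from overdent.scenarios import BASE_COSTS

from _oracles import triangular_cdf

# printed reference table: low/mode/high per remaining implant count
IMPLANT_FAILURE = {
    6: (0.014, 0.018, 0.023),
    5: (0.022, 0.0275, 0.0345),
    4: (0.030, 0.037, 0.046),
    3: (0.038, 0.0465, 0.0575),
    2: (0.046, 0.056, 0.069),
    1: (0.054, 0.0655, 0.0805),
}
DENTURE_FAILURE = {
    6: (0.015, 0.026, 0.044),
    5: (0.0185, 0.0305, 0.0565),
    4: (0.022, 0.035, 0.069),
    3: (0.0255, 0.0395, 0.0815),
    2: (0.029, 0.044, 0.094),
    1: (0.0325, 0.0485, 0.1065),
    0: (0.01, 0.05, 0.10),
}
SATISFACTION = {6: 0.89, 5: 0.89, 4: 0.89, 3: 0.865, 2: 0.84, 1: 0.735, 0: 0.63}


def triangles():
    return (
        st.tuples(
            st.floats(0, 1, allow_nan=False),
            st.floats(0, 1, allow_nan=False),
            st.floats(0, 1, allow_nan=False),
        )
        .map(sorted)
        .map(lambda t: TriangularDist(*t))
    )


class TestTriangularDist:
    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            TriangularDist(0.5, 0.4, 0.6)

    @pytest.mark.parametrize(
        "dist, expected",
        [
            ((0.0, 0.0, 0.0), 0.0),
            ((0.014, 0.018, 0.023), 0.018333333333333333),
            ((0.8, 0.9, 0.99), 0.8966666666666667),
        ],
    )
    def test_mean_closed_form(self, dist, expected):
        d = TriangularDist(*dist)
        assert triangular_mean(d) == pytest.approx(expected, rel=1e-12)
        if not d.is_degenerate:
            # numerical integration of x * density as an independent check
            rv = scipy.stats.triang(
                c=(d.mode - d.low) / (d.high - d.low), loc=d.low, scale=d.high - d.low
            )
            assert triangular_mean(d) == pytest.approx(rv.mean(), rel=1e-9)

    def test_ppf_degenerate_point_mass(self):
        d = TriangularDist(0.5, 0.5, 0.5)
        assert all(sample_triangular(d, u) == 0.5 for u in (0.0, 0.3, 1.0))

    def test_ppf_symmetric_unit_triangle(self):
        # analytic inverse CDF: F(0.25) = 0.125 on Triangular(0, 0.5, 1)
        assert sample_triangular(TriangularDist(0, 0.5, 1), 0.125) == pytest.approx(0.25)

    def test_ppf_matches_scipy(self):
        d = TriangularDist(0.015, 0.026, 0.044)
        u = np.linspace(0.0, 1.0, 101)
        rv = scipy.stats.triang(
            c=(d.mode - d.low) / (d.high - d.low), loc=d.low, scale=d.high - d.low
        )
        np.testing.assert_allclose(triangular_ppf(u, d.low, d.mode, d.high), rv.ppf(u), atol=1e-12)

    def test_ppf_rejects_u_outside_unit_interval(self):
        with pytest.raises(ValueError):
            sample_triangular(TriangularDist(0, 0.5, 1), 1.5)

    def test_sample_mean_converges_to_closed_form(self):
        d = TriangularDist(0.015, 0.026, 0.044)
        rng = np.random.default_rng(7)
        x = sample_triangular(d, rng.random(100_000))
        se = x.std(ddof=1) / np.sqrt(x.size)
        assert abs(x.mean() - triangular_mean(d)) < 3 * se

    def test_empirical_cdf_matches_analytic(self):
        # KS distance below the 1% critical value for n = 1e5
        d = TriangularDist(0.015, 0.026, 0.044)
        rng = np.random.default_rng(11)
        x = sample_triangular(d, rng.random(100_000))
        stat = scipy.stats.kstest(x, lambda q: triangular_cdf(q, d.low, d.mode, d.high)).statistic
        assert stat < 1.63 / np.sqrt(x.size)

    @given(d=triangles(), u=st.floats(0, 1, allow_nan=False))
    def test_ppf_stays_within_support(self, d, u):
        x = sample_triangular(d, u)
        assert d.low <= x <= d.high

    @given(d=triangles(), u1=st.floats(0, 1), u2=st.floats(0, 1))
    def test_ppf_monotone_in_u(self, d, u1, u2):
        lo, hi = sorted((u1, u2))
        assert sample_triangular(d, lo) <= sample_triangular(d, hi)


class TestFailureInterpolation:
    def test_reconstructs_printed_table_bit_exact(self, base):
        """The four six/four-implant anchors regenerate every printed
        interpolated low/mode/high cell exactly as a decimal."""
        for count, cells in IMPLANT_FAILURE.items():
            d = base.failure.implant[count]
            assert (d.low, d.mode, d.high) == cells, f"implant failure at {count}"
        for count, cells in DENTURE_FAILURE.items():
            d = base.failure.denture[count]
            assert (d.low, d.mode, d.high) == cells, f"denture failure at {count}"

    def test_count_zero_implant_failure_is_structural_zero(self, base):
        assert base.failure.implant[0] == TriangularDist.point(0.0)

    def test_equal_anchors_give_constant_table(self):
        d = TriangularDist(0.01, 0.02, 0.03)
        d_hi = TriangularDist(0.011, 0.021, 0.031)
        table = interpolate_failure_table(
            d, d_hi, TriangularDist.point(0.05), denture_six=d, denture_four=d_hi
        )
        # zero slope within each triple only when anchors coincide; here the
        # mode ordering is enforced, so check the degenerate-slope case per field
        assert table.implant[5].mode == pytest.approx((0.02 + 0.021) / 2)

    def test_extrapolation_leaving_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            interpolate_failure_table(
                TriangularDist(0.0, 0.1, 0.2),
                TriangularDist(0.3, 0.5, 0.9),  # count 1 high extrapolates to > 1
                TriangularDist.point(0.05),
                denture_six=TriangularDist(0.01, 0.02, 0.03),
                denture_four=TriangularDist(0.02, 0.03, 0.04),
            )

    def test_inverted_mode_ordering_rejected(self):
        lo = TriangularDist(0.01, 0.02, 0.03)
        hi = TriangularDist(0.02, 0.04, 0.05)
        with pytest.raises(ValueError, match="mode"):
            interpolate_failure_table(
                hi, lo, TriangularDist.point(0.05), denture_six=lo, denture_four=hi
            )


class TestSatisfactionInterpolation:
    def test_reproduces_printed_values(self, base):
        assert dict(base.satisfaction.scores) == SATISFACTION

    @pytest.mark.parametrize(
        "anchors, expected",
        [
            ({6: 1.0, 4: 1.0, 2: 1.0, 0: 1.0}, {5: 1.0, 3: 1.0, 1: 1.0}),
            ({6: 0.9, 4: 0.7, 2: 0.5, 0: 0.1}, {5: 0.8, 3: 0.6, 1: 0.3}),
        ],
    )
    def test_midpoint_rule(self, anchors, expected):
        scores = interpolate_satisfaction(anchors)
        for count, value in expected.items():
            assert scores[count] == pytest.approx(value, abs=1e-15)

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            interpolate_satisfaction({6: 0.7, 4: 0.8, 2: 0.6, 0: 0.5})


class TestCostSchedule:
    @pytest.mark.parametrize(
        "item, factor, expected",
        [
            ("six_new", 1.0, 1472.67),
            ("six_new", 2.3, 2990.86),
            ("six_new", 3.5, 4392.27),
            ("four_new", 2.3, 2199.98),
            ("repair_implant", 1.0, 206.68),
            ("repair_denture", 1.0, 65.19),
            ("repair_denture", 3.5, 103.16),
        ],
    )
    def test_anchor_factors_exact(self, item, factor, expected):
        assert labor_cost_at_factor(BASE_COSTS, item, factor) == expected

    def test_between_anchors_piecewise_linear(self):
        mid = labor_cost_at_factor(BASE_COSTS, "six_new", 1.65)
        assert mid == pytest.approx((1472.67 + 2990.86) / 2)

    @given(
        item=st.sampled_from(["six_new", "four_new", "repair_implant", "repair_denture"]),
        f1=st.floats(1.0, 3.5),
        f2=st.floats(1.0, 3.5),
    )
    def test_monotone_in_factor(self, item, f1, f2):
        lo, hi = sorted((f1, f2))
        assert labor_cost_at_factor(BASE_COSTS, item, lo) <= labor_cost_at_factor(
            BASE_COSTS, item, hi
        )

    def test_unknown_item_rejected(self):
        with pytest.raises(KeyError):
            labor_cost_at_factor(BASE_COSTS, "crown", 2.3)

    def test_factor_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            labor_cost_at_factor(BASE_COSTS, "six_new", 0.5)

    def test_six_implant_cost_dominance_enforced(self):
        labor = {k: tuple(v) for k, v in BASE_COSTS.labor.items()}
        labor["six_new"] = (1000.0, 2000.0, 3000.0)  # below four_new at 2.3/3.5
        with pytest.raises(ValueError, match="exceed"):
            CostSchedule(factors=(1.0, 2.3, 3.5), labor=labor, material=dict(BASE_COSTS.material))
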