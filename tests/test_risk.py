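"""Risk-translation calculators: published-arithmetic cells, inverses, CIs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bmimr import (
    WeightChange,
    absolute_risk_reduction,
    prevalence_after,
    propagate_ci,
    relative_risk_reduction,
    render_percent,
    render_weight,
    weight_for_absolute_reduction,
    weight_for_relative_reduction,
)

H = 1.7  # the worked examples all use a 1.7-m-tall individual


class TestForwardCalculators:
    def test_in_text_worked_example_48_percent(self):
        assert render_percent(relative_risk_reduction(1.30, 2.5)) == "48%"

    def test_no_change_no_reduction(self):
        assert relative_risk_reduction(1.5, 0.0) == 0.0
        assert prevalence_after(0.1, 1.0, 3.0) == pytest.approx(0.1)

    @pytest.mark.parametrize(
        "or_v,kg,expected",
        [(1.36, 2.3, "22%"), (1.25, 2.3, "16%"), (1.36, 9.1, "62%"), (1.25, 5.0, "32%")],
    )
    def test_weight_loss_relative_reduction_cells(self, or_v, kg, expected):
        assert render_percent(relative_risk_reduction(or_v, kg / H**2)) == expected

    @pytest.mark.parametrize(
        "P,or_v,expected",
        [(0.024, 1.31, "1.8%"), (0.052, 1.36, "3.8%"), (0.124, 1.25, "9.9%")],
    )
    def test_prevalence_after_one_unit(self, P, or_v, expected):
        assert render_percent(prevalence_after(P, or_v, 1.0), 1) == expected

    @pytest.mark.parametrize(
        "P,or_v,expected",
        [(0.024, 1.31, "0.6%"), (0.052, 1.36, "1.4%"), (0.124, 1.25, "2.5%")],
    )
    def test_absolute_reduction_one_unit(self, P, or_v, expected):
        assert render_percent(absolute_risk_reduction(P, or_v, 1.0), 1) == expected

    def test_absolute_equals_prevalence_times_relative(self):
        P, b, d = 0.07, 1.28, 1.7
        assert absolute_risk_reduction(P, b, d) == pytest.approx(
            P * relative_risk_reduction(b, d), abs=1e-12
        )


class TestInverseCalculators:
    @pytest.mark.parametrize(
        "or_v,target,expected",
        [
            (1.25, 0.50, "20 lbs/9 kg"),
            (1.36, 0.25, "6 lbs/3 kg"),
            (1.36, 0.50, "14 lbs/6 kg"),
            (1.25, 0.25, "8 lbs/4 kg"),
        ],
    )
    def test_weight_for_relative_reduction_cells(self, or_v, target, expected):
        kg, _ = weight_for_relative_reduction(or_v, target, H)
        assert render_weight(kg) == expected

    @pytest.mark.parametrize(
        "P,or_v,target,expected",
        [(0.124, 1.25, 0.01, "2 lbs/1 kg"), (0.124, 1.25, 0.02, "5 lbs/2 kg")],
    )
    def test_weight_for_absolute_reduction_cells(self, P, or_v, target, expected):
        kg, _ = weight_for_absolute_reduction(P, or_v, target, H)
        assert render_weight(kg) == expected

    def test_weight_ci_cell_inverts_bounds(self):
        # obese 25% relative row: weaker OR bound needs more weight
        op = lambda b: weight_for_relative_reduction(b, 0.25, H)
        (kg_lo, _), (kg_hi, _) = propagate_ci(op, (1.20, 1.31))
        assert (render_weight(kg_lo), render_weight(kg_hi)) == ("7 lbs/3 kg", "10 lbs/5 kg")

    def test_errors(self):
        with pytest.raises(ValueError):
            weight_for_relative_reduction(0.95, 0.5, H)
        with pytest.raises(ValueError):
            weight_for_absolute_reduction(0.05, 1.3, 0.06, H)


class TestPropagateCi:
    def test_table4_ci_cell_from_exact_pounds(self):
        # the printed interval derives from the exact 5-lb mass
        delta = WeightChange.from_lbs(5, H).delta_bmi
        lo, hi = propagate_ci(lambda b: relative_risk_reduction(b, delta), (1.28, 1.45))
        assert (render_percent(lo), render_percent(hi)) == ("18%", "25%")

    def test_degenerate_ci(self):
        lo, hi = propagate_ci(lambda b: relative_risk_reduction(b, 1.0), (1.3, 1.3))
        assert lo == hi == relative_risk_reduction(1.3, 1.0)

    def test_point_estimate_inside_interval_for_every_op(self):
        P, ci, beta = 0.124, (1.20, 1.31), 1.25
        ops = [
            lambda b: relative_risk_reduction(b, 1.5),
            lambda b: prevalence_after(P, b, 1.5),
            lambda b: absolute_risk_reduction(P, b, 1.5),
            lambda b: weight_for_relative_reduction(b, 0.3, H)[0],
            lambda b: weight_for_absolute_reduction(P, b, 0.02, H)[0],
        ]
        for op in ops:
            lo, hi = propagate_ci(op, ci)
            assert lo <= op(beta) <= hi


class TestWeightChange:
    def test_pounds_conversion_is_exact(self):
        wc = WeightChange.from_lbs(10, H)
        assert wc.kg == pytest.approx(4.5359237, abs=1e-12)
        assert wc.lbs == pytest.approx(10.0, abs=1e-12)
        assert wc.delta_bmi == pytest.approx(wc.kg / H**2, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            WeightChange(-1.0, H)
        with pytest.raises(ValueError):
            WeightChange(1.0, 3.0)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    beta=st.floats(1.01, 2.0),
    delta=st.floats(1e-6, 5.0),
    prev=st.floats(0.005, 0.3),
)
def test_inverse_identities_and_monotonicity(beta, delta, prev):
    """Forward/inverse pairs are exact inverses; reductions compose multiplicatively."""
    r = relative_risk_reduction(beta, delta)
    kg, lbs = weight_for_relative_reduction(beta, r, H)
    assert kg / H**2 == pytest.approx(delta, rel=1e-10)
    assert lbs == pytest.approx(kg / 0.45359237, rel=1e-12)

    arr = absolute_risk_reduction(prev, beta, delta)
    if 0 < arr < prev:
        kg2, _ = weight_for_absolute_reduction(prev, beta, arr, H)
        assert kg2 / H**2 == pytest.approx(delta, rel=1e-9)

    # strict monotonicity in effect size and dose
    assert relative_risk_reduction(beta + 0.01, delta) > r
    assert relative_risk_reduction(beta, delta + 0.01) > r
    assert absolute_risk_reduction(prev + 0.01, beta, delta) > arr

    # survival factors compose: r(d1) then r(d2) equals r(d1 + d2)
    d1, d2 = 0.4 * delta, 0.6 * delta
    composed = 1.0 - (1.0 - relative_risk_reduction(beta, d1)) * (
        1.0 - relative_risk_reduction(beta, d2)
    )
    assert composed == pytest.approx(relative_risk_reduction(beta, delta), abs=1e-12)


def test_render_weight_dialect_uses_rounded_pounds():
    # 6.515 kg -> 14.363 lbs -> "14 lbs"; displayed kg from the rounded pounds
    # (direct kg rounding would print 7 kg)
    kg, _ = weight_for_relative_reduction(1.36, 0.5, H)
    assert round(kg) == 7 and render_weight(kg) == "14 lbs/6 kg"


def test_render_percent_rounds_half_away_from_zero():
    # dyadic fractions so the half-way case is exact in binary
    assert render_percent(0.125, 0) == "13%"
    assert render_percent(0.0625, 1) == "6.3%"
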