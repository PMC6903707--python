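"""IVW / MR-Egger / Wald ratio against weighted-regression oracles."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from bmimr import MREstimate, egger, ivw, or_difference_test, orient_positive, se_from_ci, wald_ratio


def inst(rows):
    return pd.DataFrame(rows, columns=["variant_id", "beta_x", "se_x", "beta_y", "se_y"])


FIVE = inst(
    [
        ("v1", 0.08, 0.01, 0.020, 0.008),
        ("v2", 0.12, 0.012, 0.031, 0.010),
        ("v3", 0.05, 0.009, 0.012, 0.012),
        ("v4", 0.20, 0.015, 0.055, 0.009),
        ("v5", 0.10, 0.011, 0.024, 0.011),
    ]
)


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = wald_ratio({"beta_x": 0.1, "beta_y": 0.05, "se_y": 0.01})
        assert est.log_or == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_effect(self):
        est = wald_ratio({"beta_x": 1.0, "beta_y": 0.0, "se_y": 0.2})
        assert est.log_or == 0.0
        assert est.odds_ratio == 1.0

    def test_orientation_invariance(self):
        a = wald_ratio({"beta_x": 0.1, "beta_y": 0.05, "se_y": 0.01})
        b = wald_ratio({"beta_x": -0.1, "beta_y": -0.05, "se_y": 0.01})
        assert (a.log_or, a.se) == (b.log_or, b.se)

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(ValueError):
            wald_ratio({"beta_x": 0.0, "beta_y": 0.1, "se_y": 0.1})


class TestIvw:
    def test_consensus_ratio(self):
        est = ivw(inst([("a", 0.1, 0.01, 0.05, 0.01), ("b", 0.2, 0.01, 0.10, 0.02)]))
        assert est.log_or == pytest.approx(0.5, abs=1e-12)

    def test_single_instrument_equals_wald(self):
        one = inst([("a", 0.1, 0.01, 0.04, 0.02)])
        est = ivw(one)
        wald = wald_ratio(one.iloc[0])
        assert est.log_or == pytest.approx(wald.log_or, abs=1e-15)
        assert est.se == pytest.approx(wald.se, abs=1e-15)
        assert est.q_p is None

    def test_five_instrument_fixture_matches_wls_through_origin(self):
        est = ivw(FIVE)
        w = 1.0 / FIVE["se_y"] ** 2
        oracle = sm.WLS(FIVE["beta_y"], FIVE[["beta_x"]], weights=w).fit()
        assert est.log_or == pytest.approx(oracle.params.iloc[0], abs=1e-12)
        # fixed-effect SE: WLS SE with the residual scale divided back out
        fe_se = oracle.bse.iloc[0] / np.sqrt(oracle.scale)
        assert est.se == pytest.approx(fe_se, abs=1e-12)

    def test_sign_flip_invariance(self):
        flipped = FIVE.copy()
        flipped.loc[2, ["beta_x", "beta_y"]] *= -1
        a, b = ivw(FIVE), ivw(flipped)
        assert a.log_or == pytest.approx(b.log_or, abs=1e-14)
        assert a.q_stat == pytest.approx(b.q_stat, abs=1e-12)

    def test_se_not_larger_than_best_single_wald_se(self):
        best = min(wald_ratio(row).se for _, row in FIVE.iterrows())
        assert ivw(FIVE).se <= best + 1e-15

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ivw(inst([]))


class TestEgger:
    def test_exact_fit_recovers_intercept_and_slope(self):
        bx = np.array([0.05, 0.08, 0.1, 0.15, 0.2])
        df = inst(
            [(f"v{i}", bx[i], 0.01, 0.01 + 0.5 * bx[i], 0.01) for i in range(5)]
        )
        res = egger(df)
        assert res.intercept == pytest.approx(0.01, abs=1e-12)
        assert res.slope.log_or == pytest.approx(0.5, abs=1e-12)

    def test_pleiotropy_fixture_matches_wls_oracle(self):
        df = FIVE.copy()
        extra = inst([("v6", 0.15, 0.013, 0.040, 0.010)])
        df = pd.concat([df, extra], ignore_index=True)
        df.loc[[1, 3], "beta_y"] += 0.05  # directional pleiotropy in two instruments
        res = egger(df)
        w = 1.0 / df["se_y"] ** 2
        X = sm.add_constant(df["beta_x"])
        oracle = sm.WLS(df["beta_y"], X, weights=w).fit()
        assert res.intercept == pytest.approx(oracle.params.iloc[0], abs=1e-10)
        assert res.slope.log_or == pytest.approx(oracle.params.iloc[1], abs=1e-10)
        # multiplicative random-effects scale: here residual scale > 1, so the
        # SEs coincide with the WLS (estimated-scale) standard errors
        assert oracle.scale > 1
        assert res.intercept_se == pytest.approx(oracle.bse.iloc[0], abs=1e-10)
        assert res.slope.se == pytest.approx(oracle.bse.iloc[1], abs=1e-10)
        assert res.intercept_p == pytest.approx(oracle.pvalues.iloc[0], abs=1e-10)

    def test_residual_scale_floored_at_one(self):
        # near-exact fit: residual scale < 1 must not shrink the SEs below
        # the fixed-effect (unit-scale) normal-equation values
        bx = np.array([0.05, 0.08, 0.1, 0.15, 0.2])
        df = inst([(f"v{i}", bx[i], 0.01, 0.5 * bx[i] + 1e-6 * i, 0.01) for i in range(5)])
        res = egger(df)
        w = np.full(5, 1.0 / 0.01**2)
        X = np.column_stack([np.ones(5), bx])
        cov = np.linalg.inv((X * w[:, None]).T @ X)
        assert res.slope.se == pytest.approx(math.sqrt(cov[1, 1]), abs=1e-12)

    def test_too_few_or_degenerate_instruments(self):
        with pytest.raises(ValueError, match="at least 3"):
            egger(FIVE.iloc[:2])
        same = inst([(f"v{i}", 0.1, 0.01, 0.05, 0.01) for i in range(4)])
        with pytest.raises(ValueError, match="rank"):
            egger(same)

    def test_through_origin_fit_equals_ivw(self):
        # removing the intercept column from the Egger design is exactly IVW
        w = 1.0 / FIVE["se_y"] ** 2
        oracle = sm.WLS(FIVE["beta_y"], FIVE[["beta_x"]], weights=w).fit()
        assert ivw(FIVE).log_or == pytest.approx(oracle.params.iloc[0], abs=1e-10)


class TestSeFromCi:
    @pytest.mark.parametrize(
        "or_v,lo,hi,expected",
        [(1.36, 1.28, 1.45, 0.0318), (1.25, 1.20, 1.31, 0.0224)],
    )
    def test_printed_ci_reconstruction(self, or_v, lo, hi, expected):
        assert se_from_ci(or_v, lo, hi) == pytest.approx(expected, abs=2e-4)

    def test_symmetric_ci_round_trip(self):
        or_v, se = 1.3, 0.05
        lo, hi = math.exp(math.log(or_v) - 1.96 * se), math.exp(math.log(or_v) + 1.96 * se)
        assert se_from_ci(or_v, lo, hi) == pytest.approx(se, abs=1e-12)

    def test_ordering_violation(self):
        with pytest.raises(ValueError):
            se_from_ci(1.2, 1.25, 1.3)


class TestOrDifference:
    def _est(self, or_v, lo, hi):
        return MREstimate(math.log(or_v), se_from_ci(or_v, lo, hi), (lo, hi), 10, "ivw")

    def test_identical_estimates(self):
        e = self._est(1.3, 1.2, 1.4)
        z, p = or_difference_test(e, e)
        assert z == 0.0 and p == 1.0

    def test_overweight_vs_obese_published_comparison(self):
        z, p = or_difference_test(self._est(1.36, 1.28, 1.45), self._est(1.25, 1.20, 1.31))
        assert round(p, 2) == 0.03

    def test_antisymmetry(self):
        a, b = self._est(1.36, 1.28, 1.45), self._est(1.25, 1.20, 1.31)
        z1, p1 = or_difference_test(a, b)
        z2, p2 = or_difference_test(b, a)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    bx=st.lists(st.floats(0.02, 0.5), min_size=2, max_size=8),
    ratios=st.floats(-1.0, 1.0),
    seed=st.integers(0, 1000),
)
def test_ivw_joint_flip_invariance_property(bx, ratios, seed):
    rng = np.random.default_rng(seed)
    df = inst(
        [
            (f"v{i}", b, 0.01, ratios * b + 0.01 * rng.standard_normal(), 0.01 + 0.005 * (i % 3))
            for i, b in enumerate(bx)
        ]
    )
    flip = df.copy()
    signs = np.where(np.arange(len(df)) % 2 == 0, -1.0, 1.0)
    flip[["beta_x", "beta_y"]] = flip[["beta_x", "beta_y"]].mul(signs, axis=0)
    assert ivw(df).log_or == pytest.approx(ivw(flip).log_or, abs=1e-12)
    oriented = orient_positive(flip)
    assert (oriented["beta_x"] > 0).all()
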