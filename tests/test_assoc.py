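"""Association scans against independent oracles, HWE mid-p, instrument QC."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import gammaln

from bmimr import filter_instruments, hwe_midp, linear_assoc, logistic_assoc

from conftest import make_genotypes


def hwe_midp_oracle(n_hom_ref, n_het, n_hom_alt):
    """Brute-force enumeration of the exact conditional HWE mid-p.

    Direct implementation from the hypergeometric configuration probability
    P(h | n, n_rare) = n! 2^h / (h! n_rh! n_ch!) * n_rare! n_common! / (2n)!
    summed over every heterozygote count with the right parity.
    """
    n = n_hom_ref + n_het + n_hom_alt
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if rare == 0:
        return 1.0

    def logprob(h):
        n_rh = (rare - h) // 2
        n_ch = n - h - n_rh
        return (
            gammaln(n + 1) + h * math.log(2) - gammaln(h + 1) - gammaln(n_rh + 1)
            - gammaln(n_ch + 1) + gammaln(rare + 1) + gammaln(2 * n - rare + 1)
            - gammaln(2 * n + 1)
        )

    hs = list(range(rare % 2, rare + 1, 2))
    probs = np.exp([logprob(h) for h in hs])
    probs = probs / probs.sum()
    p_obs = probs[hs.index(n_het)]
    return float(probs[probs < p_obs].sum() + 0.5 * p_obs)


class TestLinearAssoc:
    def test_exact_linear_relation(self):
        d = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        stats = linear_assoc(make_genotypes(d), 2.0 * d)
        assert stats.loc[0, "beta"] == pytest.approx(2.0, abs=1e-12)
        assert stats.loc[0, "se"] == pytest.approx(0.0, abs=1e-10)

    def test_eight_point_fixture_matches_closed_form(self):
        d = np.array([0, 0, 1, 1, 1, 2, 2, 2], dtype=float)
        y = np.array([1, 2, 2, 3, 3, 4, 4, 5], dtype=float)
        # independent closed-form least squares on the 8 points
        sxx = ((d - d.mean()) ** 2).sum()
        sxy = ((d - d.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        resid = y - (y.mean() + slope * (d - d.mean()))
        se = math.sqrt((resid @ resid) / (len(d) - 2) / sxx)
        stats = linear_assoc(make_genotypes(d), y)
        assert stats.loc[0, "beta"] == pytest.approx(slope, abs=1e-10)
        assert stats.loc[0, "se"] == pytest.approx(se, abs=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, 40).astype(float)
        y = d * 0.5 + rng.standard_normal(40)
        perm = rng.permutation(40)
        a = linear_assoc(make_genotypes(d), y)
        b = linear_assoc(make_genotypes(d[perm]), y[perm])
        for col in ("beta", "se", "p", "n_used"):
            assert a.loc[0, col] == pytest.approx(b.loc[0, col], abs=1e-12)

    def test_matches_statsmodels_with_covariates_and_missingness(self):
        rng = np.random.default_rng(1)
        n = 200
        d = rng.integers(0, 3, (n, 3)).astype(float)
        d[rng.random((n, 3)) < 0.1] = np.nan
        C = rng.standard_normal((n, 2))
        y = np.nansum(d, axis=1) * 0.3 + C @ [1.0, -0.5] + rng.standard_normal(n)
        stats = linear_assoc(make_genotypes(d), y, C)
        for j in range(3):
            keep = ~np.isnan(d[:, j])
            X = sm.add_constant(np.column_stack([d[keep, j], C[keep]]))
            fit = sm.OLS(y[keep], X).fit()
            assert stats.loc[j, "beta"] == pytest.approx(fit.params[1], abs=1e-8)
            assert stats.loc[j, "se"] == pytest.approx(fit.bse[1], abs=1e-8)
            assert stats.loc[j, "p"] == pytest.approx(fit.pvalues[1], abs=1e-8)
            assert stats.loc[j, "n_used"] == keep.sum()

    def test_rank_deficient_design_names_column(self):
        d = np.array([0.0, 1.0, 2.0, 1.0])
        C = np.column_stack([np.ones(4), np.arange(4.0)])  # first column duplicates intercept
        with pytest.raises(ValueError, match="covar_0"):
            linear_assoc(make_genotypes(d), np.zeros(4), C)

    def test_all_missing_variant_flagged(self):
        d = np.full((10, 1), np.nan)
        stats = linear_assoc(make_genotypes(d), np.zeros(10))
        assert stats.loc[0, "n_used"] == 0
        assert bool(stats.loc[0, "failed"])


class TestLogisticAssoc:
    def test_two_by_two_matches_odds_ratio(self):
        # dosage 1: 10 cases / 20 controls;  dosage 0: 30 cases / 40 controls
        d = np.concatenate([np.ones(30), np.zeros(70)])
        y = np.concatenate([np.ones(10), np.zeros(20), np.ones(30), np.zeros(40)])
        stats = logistic_assoc(make_genotypes(d), y)
        assert stats.loc[0, "beta"] == pytest.approx(math.log((10 * 40) / (20 * 30)), abs=1e-6)
        assert stats.loc[0, "se"] == pytest.approx(
            math.sqrt(1 / 10 + 1 / 20 + 1 / 30 + 1 / 40), abs=1e-6
        )

    def test_allele_flip_negates_beta(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, 500).astype(float)
        y = rng.random(500) < 0.3
        a = logistic_assoc(make_genotypes(d), y)
        b = logistic_assoc(make_genotypes(2.0 - d), y)
        assert a.loc[0, "beta"] == pytest.approx(-b.loc[0, "beta"], abs=1e-8)
        assert a.loc[0, "se"] == pytest.approx(b.loc[0, "se"], abs=1e-8)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        n = 300
        d = rng.integers(0, 3, (n, 2)).astype(float)
        C = rng.standard_normal((n, 1))
        logit = -1.0 + 0.4 * d[:, 0] + 0.5 * C[:, 0]
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        stats = logistic_assoc(make_genotypes(d), y, C)
        for j in range(2):
            X = sm.add_constant(np.column_stack([d[:, j], C]))
            fit = sm.Logit(y.astype(float), X).fit(disp=0, method="newton", tol=1e-12)
            assert stats.loc[j, "beta"] == pytest.approx(fit.params[1], abs=1e-8)
            assert stats.loc[j, "se"] == pytest.approx(fit.bse[1], abs=1e-8)

    def test_null_calibration_rejection_rate(self):
        # 500 independent null variants, n=5,000: Wald test at 0.05 rejects ~5%
        rng = np.random.default_rng(4)
        n, m = 5_000, 500
        d = rng.binomial(2, 0.3, (n, m)).astype(float)
        y = rng.random(n) < 0.1
        stats = logistic_assoc(make_genotypes(d, ids=[f"v{j}" for j in range(m)]), y)
        rate = (stats["p"] < 0.05).mean()
        assert abs(rate - 0.05) < 0.02

    def test_perfect_separation_flagged_not_fatal(self):
        d = np.concatenate([np.zeros(20), np.full(20, 2.0)])
        y = np.concatenate([np.zeros(20), np.ones(20)])
        stats = logistic_assoc(make_genotypes(d), y)
        assert bool(stats.loc[0, "failed"])

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            logistic_assoc(make_genotypes(np.arange(4.0) % 3), np.ones(4))


class TestHweMidp:
    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (0, 2, 0), (10, 5, 1), (100, 10, 40), (3, 0, 3), (50, 21, 4)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_midp(*counts) == pytest.approx(hwe_midp_oracle(*counts), rel=1e-12)

    def test_two_individual_case_by_hand(self):
        # n=2, minor count 2: P(h=2)=2/3, P(h=0)=1/3 -> midp = 1/3 + 0.5*2/3
        assert hwe_midp(0, 2, 0) == pytest.approx(1 / 3 + 0.5 * 2 / 3, rel=1e-12)

    def test_label_swap_symmetry(self):
        for a, b, c in [(12, 7, 3), (0, 5, 9), (4, 4, 4)]:
            assert hwe_midp(a, b, c) == pytest.approx(hwe_midp(c, b, a), rel=1e-12)

    def test_monomorphic_returns_one(self):
        assert hwe_midp(30, 0, 0) == 1.0

    def test_monotone_in_heterozygote_excess(self):
        # fixed allele counts (n=60, 60 minor alleles): mid-p decreases as the
        # heterozygote count moves above its modal (HWE-expected) value
        ps = [hwe_midp((60 - h) // 2, h, (60 - h) // 2) for h in range(30, 61, 2)]
        assert all(ps[i] >= ps[i + 1] - 1e-12 for i in range(len(ps) - 1))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_midp(-1, 0, 2)
        with pytest.raises(ValueError):
            hwe_midp(0, 0, 0)


class TestFilterInstruments:
    def _stats(self, rows):
        import pandas as pd

        return pd.DataFrame(
            rows, columns=["variant_id", "missing_rate", "hwe_midp"]
        ).assign(beta=0.1, se=0.05, p=0.5, n_used=100, effect_allele="A", failed=False)

    def test_boundaries_are_strict(self):
        stats = self._stats([("a", 0.10, 0.5), ("b", 0.05, 1e-20), ("c", 0.0999, 1.1e-20)])
        kept, reasons = filter_instruments(stats, allowed_ids=["a", "b", "c"])
        assert kept == ["c"]
        assert "missing_rate" in reasons["a"] and "hwe_midp" in reasons["b"]

    def test_five_variant_fixture(self):
        stats = self._stats(
            [
                ("v1", 0.0, 0.9),
                ("v2", 0.2, 0.9),     # fails missingness
                ("v3", 0.0, 1e-30),   # fails HWE
                ("v4", 0.01, 0.5),
                ("v5", 0.0, 0.2),     # not in allowed list
            ]
        )
        kept, reasons = filter_instruments(stats, allowed_ids=["v1", "v2", "v3", "v4"])
        assert kept == ["v1", "v4"]
        assert set(reasons) == {"v2", "v3", "v5"}

    def test_allowed_ids_must_be_covered(self):
        with pytest.raises(ValueError, match="vX"):
            filter_instruments(self._stats([("v1", 0.0, 0.9)]), allowed_ids=["v1", "vX"])
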