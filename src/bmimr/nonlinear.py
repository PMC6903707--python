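"""Nonlinear Mendelian randomization via quantile stratification.

A single weighted allele score summarizes the instruments; the cohort is
split into equal-size strata of the "IV-free exposure" (BMI with the score's
contribution regressed out, which avoids collider bias from stratifying on
the exposure itself). Within each stratum a localized average causal effect
(LACE) is the ratio of the score's log-OR on disease to the score's effect on
BMI. Cochran's Q tests heterogeneity of the LACE estimates across strata and
an inverse-variance-weighted linear trend on stratum mean BMI tests for a
dose-response in the effect; the same machinery applied to the score-on-BMI
coefficients checks the method's constant-instrument-strength assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from ._utils import bin_by_rank
from ._glm import _as_covariate_matrix, _logistic_irls, _ols_fit
from .simulate import GenotypeMatrix


def allele_score(genotypes: GenotypeMatrix, weights: pd.DataFrame) -> np.ndarray:
    """Weighted sum of instrument dosages, harmonized to the weights' effect alleles.

    ``weights`` needs columns ``variant_id, effect_allele, beta``. Weight rows
    whose variant is absent from the genotypes are dropped with a warning
    naming the ids; genotype variants absent from the weights are ignored.
    Missing dosages are mean-imputed per variant. If the genotype matrix
    carries effect alleles, dosages whose allele disagrees with the weight
    file are flipped (d -> 2 - d).
    """
    for col in ("variant_id", "beta"):
        if col not in weights.columns:
            raise ValueError(f"weights table is missing column '{col}'")
    present = weights["variant_id"].isin(genotypes.variant_ids)
    dropped = weights.loc[~present, "variant_id"].tolist()
    if dropped:
        warnings.warn(
            f"{len(dropped)} weight(s) absent from genotypes and excluded from the "
            f"allele score: {', '.join(dropped)}",
            stacklevel=2,
        )
    usable = weights.loc[present]
    if len(usable) == 0:
        raise ValueError("no usable weights: no weight variant appears in the genotypes")
    imputed = genotypes.mean_imputed()
    score = np.zeros(genotypes.n_individuals)
    for row in usable.itertuples(index=False):
        j = genotypes.variant_ids.index(row.variant_id)
        d = imputed[:, j]
        if (
            genotypes.effect_allele is not None
            and "effect_allele" in usable.columns
            and str(row.effect_allele) != str(genotypes.effect_allele[j])
        ):
            d = 2.0 - d
        score = score + float(row.beta) * d
    return score


@dataclass
class QuantileMRResult:
    """Per-quantile LACE estimates plus heterogeneity and trend tests."""

    per_quantile: pd.DataFrame  # quantile, n, n_cases, mean_bmi, lace_log_or,
    #                             lace_se, score_bmi_beta, score_bmi_se, valid
    q_stat_lace: float
    q_p_lace: Optional[float]
    trend_p_lace: Optional[float]
    q_stat_score_bmi: float
    q_p_score_bmi: Optional[float]
    trend_p_score_bmi: Optional[float]
    lace_ivw: float
    lace_ivw_se: float
    n_dropped: int


def _weighted_q_and_trend(est, se, x):
    """Fixed-effect Q against the IVW mean, and IVW linear trend of est on x."""
    w = 1.0 / se**2
    mean = float(np.sum(w * est) / np.sum(w))
    q = float(np.sum(w * (est - mean) ** 2))
    k = len(est)
    q_p = float(chi2.sf(q, k - 1)) if k > 1 else None
    trend_p = None
    if k > 2 and np.ptp(x) > 0:
        X = np.column_stack([np.ones(k), x])
        XtWX = (X * w[:, None]).T @ X
        coef = np.linalg.solve(XtWX, (X * w[:, None]).T @ est)
        cov = np.linalg.inv(XtWX)
        slope_se = float(np.sqrt(cov[1, 1]))
        if slope_se > 0:
            trend_p = float(2.0 * norm.sf(abs(coef[1] / slope_se)))
    return mean, float(1.0 / np.sqrt(np.sum(w))), q, q_p, trend_p


def quantile_mr(
    bmi,
    case,
    score,
    covariates=None,
    n_quantiles: int = 50,
) -> QuantileMRResult:
    """Stratified MR across equal-size quantiles of the IV-free exposure.

    Steps: (1) the IV-free exposure is the residual of BMI on the allele score
    and covariates; (2) individuals are ranked into ``n_quantiles`` equal-size
    strata (stable ties); (3) within each stratum the score's linear effect on
    BMI and logistic log-OR on case status are estimated (covariate-adjusted)
    and LACE = logistic beta / linear beta with first-order SE; (4) Cochran's
    Q across strata against the precision-weighted mean, chi-square(Q-1);
    (5) an inverse-variance-weighted linear trend of LACE on stratum mean BMI;
    (6) the same Q/trend machinery for the score-on-BMI coefficients.

    Strata whose logistic fit is degenerate (no cases, separation) are flagged
    invalid and dropped from the Q and trend tests with a logged count.
    """
    bmi = np.asarray(bmi, dtype=float)
    y = np.asarray(case, dtype=float)
    s = np.asarray(score, dtype=float)
    n = len(bmi)
    if len(y) != n or len(s) != n:
        raise ValueError("bmi, case and score must have equal length")
    if n < 20 * n_quantiles:
        raise ValueError(f"need at least {20 * n_quantiles} individuals for {n_quantiles} quantiles")
    C, _ = _as_covariate_matrix(covariates, n)

    # (1) IV-free exposure: residual of BMI on [1, score, covariates]
    X_free = np.column_stack([np.ones(n), s, C])
    coef, _, _, _ = np.linalg.lstsq(X_free, bmi, rcond=None)
    iv_free = bmi - X_free @ coef

    # (2) equal-size strata of the IV-free exposure
    bins = bin_by_rank(iv_free, n_quantiles)

    records = []
    for q in range(n_quantiles):
        sel = bins == q
        nq = int(sel.sum())
        Xq = np.column_stack([np.ones(nq), s[sel], C[sel]])
        lin_beta, lin_se, dof = _ols_fit(Xq, bmi[sel])
        sb, sb_se = float(lin_beta[1]), float(lin_se[1])
        yq = y[sel]
        n_cases = int(yq.sum())
        valid = True
        lace = lace_se = np.nan
        if n_cases == 0 or n_cases == nq or sb == 0:
            valid = False
        else:
            log_beta, log_se, ok = _logistic_irls(Xq, yq)
            if not ok or not np.isfinite(log_se[1]) or log_se[1] <= 0:
                valid = False
            else:
                lace = float(log_beta[1]) / sb
                lace_se = float(log_se[1]) / abs(sb)
        records.append([q + 1, nq, n_cases, float(bmi[sel].mean()), lace, lace_se, sb, sb_se, valid])

    per_q = pd.DataFrame(
        records,
        columns=[
            "quantile", "n", "n_cases", "mean_bmi", "lace_log_or", "lace_se",
            "score_bmi_beta", "score_bmi_se", "valid",
        ],
    )
    ok = per_q["valid"].to_numpy(bool) & (per_q["lace_se"].to_numpy(float) > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} quantile stratum/strata dropped from Q and trend tests", stacklevel=2)
    if ok.sum() == 0:
        raise RuntimeError("no quantile stratum produced a usable LACE estimate")
    lace_mean, lace_mean_se, q_l, qp_l, tp_l = _weighted_q_and_trend(
        per_q.loc[ok, "lace_log_or"].to_numpy(float),
        per_q.loc[ok, "lace_se"].to_numpy(float),
        per_q.loc[ok, "mean_bmi"].to_numpy(float),
    )
    ok_sb = per_q["score_bmi_se"].to_numpy(float) > 0
    _, _, q_s, qp_s, tp_s = _weighted_q_and_trend(
        per_q.loc[ok_sb, "score_bmi_beta"].to_numpy(float),
        per_q.loc[ok_sb, "score_bmi_se"].to_numpy(float),
        per_q.loc[ok_sb, "mean_bmi"].to_numpy(float),
    )
    return QuantileMRResult(
        per_quantile=per_q,
        q_stat_lace=q_l,
        q_p_lace=qp_l,
        trend_p_lace=tp_l,
        q_stat_score_bmi=q_s,
        q_p_score_bmi=qp_s,
        trend_p_score_bmi=tp_s,
        lace_ivw=lace_mean,
        lace_ivw_se=lace_mean_se,
        n_dropped=n_dropped,
    )
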