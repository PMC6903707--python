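"""Per-variant association scans and instrument quality control.

The exposure scan regresses a continuous phenotype (BMI) on each instrument's
dosage with ordinary least squares; the outcome scan fits a per-variant
logistic regression of case status by iteratively reweighted least squares.
Both adjust for covariates and handle missing dosages by per-variant
complete-case analysis (standard GWAS practice). Instrument QC applies the
missingness and exact Hardy-Weinberg mid-p filters.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from scipy.stats import norm, t as t_dist

from ._glm import _as_covariate_matrix, _check_full_rank, _logistic_irls, _ols_fit
from .simulate import GenotypeMatrix

STATS_COLUMNS = [
    "variant_id", "beta", "se", "p", "n_used", "missing_rate", "hwe_midp",
    "effect_allele", "failed",
]


def design_from_cohort(cohort: pd.DataFrame, n_pcs: Optional[int] = None) -> pd.DataFrame:
    """The default covariate block: age, sex, array, assessment center, PCs.

    Categorical covariates are dummy-coded dropping the first level.
    """
    cols = {"age": cohort["age"].astype(float), "sex": cohort["sex"].astype(float)}
    for cat in ("genotyping_array", "assessment_center"):
        levels = sorted(cohort[cat].astype(str).unique())
        for lev in levels[1:]:
            cols[f"{cat}={lev}"] = (cohort[cat].astype(str) == lev).astype(float)
    pc_cols = sorted(
        (c for c in cohort.columns if c.startswith("pc") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    if n_pcs is not None:
        pc_cols = pc_cols[:n_pcs]
    for c in pc_cols:
        cols[c] = cohort[c].astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def _variant_qc(dosage_col: np.ndarray) -> Tuple[float, float]:
    """(missing_rate, hwe_midp) for one variant; HWE on dosages rounded to 0/1/2."""
    miss = float(np.mean(np.isnan(dosage_col)))
    present = dosage_col[~np.isnan(dosage_col)]
    if present.size == 0:
        return miss, np.nan
    g = np.clip(np.round(present), 0, 2).astype(int)
    counts = np.bincount(g, minlength=3)
    return miss, hwe_midp(int(counts[0]), int(counts[1]), int(counts[2]))


def linear_assoc(
    genotypes: GenotypeMatrix,
    phenotype,
    covariates=None,
) -> pd.DataFrame:
    """Per-variant OLS of phenotype on [intercept, dosage, covariates].

    Complete cases per variant (rows missing that variant's dosage dropped).
    ``beta``/``se``/``p`` are the dosage coefficient's; two-sided p from the
    t distribution with n - k degrees of freedom.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.ndim != 1 or len(y) != genotypes.n_individuals:
        raise ValueError("phenotype length must equal the number of individuals")
    C, cnames = _as_covariate_matrix(covariates, len(y))
    base = np.column_stack([np.ones(len(y)), C])
    _check_full_rank(base, ["intercept"] + cnames)
    rows = []
    for j, vid in enumerate(genotypes.variant_ids):
        d = genotypes.dosage[:, j]
        miss, hwe = _variant_qc(d)
        keep = ~np.isnan(d)
        n_used = int(keep.sum())
        allele = genotypes.effect_allele[j] if genotypes.effect_allele else None
        if n_used == 0 or np.nanstd(d) == 0:
            rows.append((vid, np.nan, np.nan, np.nan, n_used, miss, hwe, allele, True))
            continue
        X = np.column_stack([np.ones(n_used), d[keep], base[keep, 1:]])
        beta, se, dof = _ols_fit(X, y[keep])
        b, s = float(beta[1]), float(se[1])
        if dof > 0 and s > 0:
            p = float(2.0 * t_dist.sf(abs(b / s), dof))
        elif s == 0:
            p = 0.0
        else:
            p = np.nan
        rows.append((vid, b, s, p, n_used, miss, hwe, allele, False))
    return pd.DataFrame(rows, columns=STATS_COLUMNS)


def logistic_assoc(
    genotypes: GenotypeMatrix,
    case,
    covariates=None,
) -> pd.DataFrame:
    """Per-variant logistic regression of case status on dosage + covariates.

    ``beta`` is the dosage log odds ratio with Wald se/p (normal reference).
    Perfect separation yields a per-variant ``failed`` flag, not an exception.
    """
    y = np.asarray(case, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("case vector must be binary")
    if y.min() == y.max():
        raise ValueError("logistic regression requires both classes present")
    if len(y) != genotypes.n_individuals:
        raise ValueError("case length must equal the number of individuals")
    C, cnames = _as_covariate_matrix(covariates, len(y))
    base = np.column_stack([np.ones(len(y)), C])
    _check_full_rank(base, ["intercept"] + cnames)
    # covariate-only fit warm-starts every per-variant iteration
    base_beta, _, base_ok = _logistic_irls(base, y)
    rows = []
    for j, vid in enumerate(genotypes.variant_ids):
        d = genotypes.dosage[:, j]
        miss, hwe = _variant_qc(d)
        keep = ~np.isnan(d)
        n_used = int(keep.sum())
        allele = genotypes.effect_allele[j] if genotypes.effect_allele else None
        yk = y[keep]
        if n_used == 0 or np.nanstd(d) == 0 or yk.min() == yk.max():
            rows.append((vid, np.nan, np.nan, np.nan, n_used, miss, hwe, allele, True))
            continue
        X = np.column_stack([np.ones(n_used), d[keep], base[keep, 1:]])
        warm = np.insert(base_beta, 1, 0.0) if base_ok else None
        beta, se, ok = _logistic_irls(X, yk, beta0=warm)
        if not ok or not np.isfinite(se[1]) or se[1] <= 0:
            rows.append((vid, float(beta[1]), np.nan, np.nan, n_used, miss, hwe, allele, True))
            continue
        b, s = float(beta[1]), float(se[1])
        p = float(2.0 * norm.sf(abs(b / s)))
        rows.append((vid, b, s, p, n_used, miss, hwe, allele, False))
    return pd.DataFrame(rows, columns=STATS_COLUMNS)


def hwe_midp(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test, mid-p variant.

    Conditions on the observed allele counts and enumerates every heterozygote
    count consistent with them; each configuration's probability under the
    HWE null is hypergeometric. The mid-p sums configurations strictly less
    probable than the observed one plus half the observed configuration's
    probability. Monomorphic variants return 1.0. Result clamped to (0, 1].
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotyped individual required")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # minor allele count
    if rare == 0:
        return 1.0
    # valid heterozygote counts share the minor-allele count's parity;
    # for each, n_rare_hom = (rare - h)/2 and n_common_hom = n - h - n_rare_hom >= 0
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(n_common_hom + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = np.where(hets == n_het)[0]
    if obs.size != 1:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    p_obs = probs[obs[0]]
    midp = float(probs[probs < p_obs].sum() + 0.5 * p_obs)
    return float(min(max(midp, np.finfo(float).tiny), 1.0))


def filter_instruments(
    stats: pd.DataFrame,
    max_missing: float = 0.1,
    min_hwe_midp: float = 1e-20,
    allowed_ids: Optional[Sequence[str]] = None,
) -> Tuple[List[str], Dict[str, str]]:
    """Keep variants with missing_rate < max_missing, hwe_midp > min_hwe_midp,
    and id in allowed_ids (both thresholds strict). Order preserved.

    Returns (kept_ids, rejection reason per rejected id).
    """
    if allowed_ids is not None:
        allowed = set(allowed_ids)
        missing_stats = allowed - set(stats["variant_id"])
        if missing_stats:
            raise ValueError(f"stats do not cover allowed ids: {sorted(missing_stats)}")
    kept: List[str] = []
    reasons: Dict[str, str] = {}
    for row in stats.itertuples(index=False):
        vid = row.variant_id
        if allowed_ids is not None and vid not in allowed:
            reasons[vid] = "not in allowed list"
        elif not (row.missing_rate < max_missing):
            reasons[vid] = f"missing_rate {row.missing_rate:.4f} >= {max_missing}"
        elif not (row.hwe_midp > min_hwe_midp):
            reasons[vid] = f"hwe_midp {row.hwe_midp:.3g} <= {min_hwe_midp}"
        else:
            kept.append(vid)
    return kept, reasons
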