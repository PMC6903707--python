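"""Causal-effect estimation from instrument-level summary statistics.

Implements the standard two-stage summary-data Mendelian randomization
estimators: per-instrument Wald ratios, the fixed-effect inverse-variance-
weighted (IVW) combination with Cochran's Q heterogeneity statistic, and
MR-Egger regression with the intercept test for directional pleiotropy
(multiplicative random-effects scaling of the standard errors). Helpers
reconstruct log-OR standard errors from printed confidence intervals and
compare two estimates with a difference-of-odds-ratios z test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, t as t_dist

INSTRUMENT_COLUMNS = ["variant_id", "beta_x", "se_x", "beta_y", "se_y"]

Z95 = 1.96  # conventional two-sided 95% normal quantile used for printed CIs


@dataclass
class MREstimate:
    """A causal log odds ratio per unit of exposure (1 kg/m^2 BMI)."""

    log_or: float
    se: float
    ci95: Tuple[float, float]  # on the OR scale
    n_instruments: int
    method: str
    q_stat: Optional[float] = None
    q_p: Optional[float] = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.log_or))

    def covers(self, log_or: float) -> bool:
        lo, hi = self.ci95
        return lo <= np.exp(log_or) <= hi


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float


def _validate(instruments: pd.DataFrame) -> pd.DataFrame:
    if len(instruments) == 0:
        raise ValueError("at least one instrument required")
    missing = set(INSTRUMENT_COLUMNS) - set(instruments.columns)
    if missing:
        raise ValueError(f"instrument table is missing columns: {sorted(missing)}")
    if instruments["variant_id"].duplicated().any():
        raise ValueError("instrument variant_ids must be unique")
    if (instruments["se_x"] <= 0).any() or (instruments["se_y"] <= 0).any():
        raise ValueError("instrument standard errors must be positive")
    return instruments


def orient_positive(instruments: pd.DataFrame) -> pd.DataFrame:
    """Re-orient effect alleles so every exposure beta is positive.

    Jointly flips the sign of (beta_x, beta_y); IVW is invariant to this but
    the Egger intercept is orientation-sensitive, so a deterministic
    convention is required before calling :func:`egger`.
    """
    out = _validate(instruments).copy()
    flip = out["beta_x"] < 0
    out.loc[flip, ["beta_x", "beta_y"]] *= -1.0
    return out


def wald_ratio(instrument) -> MREstimate:
    """Single-instrument causal estimate: beta_y / beta_x with first-order SE."""
    bx = float(instrument["beta_x"])
    by = float(instrument["beta_y"])
    sy = float(instrument["se_y"])
    if bx == 0:
        raise ValueError("wald_ratio undefined for beta_x = 0")
    log_or = by / bx
    se = sy / abs(bx)
    ci = (float(np.exp(log_or - Z95 * se)), float(np.exp(log_or + Z95 * se)))
    return MREstimate(log_or, se, ci, 1, "wald")


def ivw(instruments: pd.DataFrame) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    Equivalent to weighted least squares of beta_y on beta_x through the
    origin with weights 1/se_y^2 (exposure SEs ignored: first-order weights).
    Cochran's Q is referred to chi-square with n-1 df (undefined for a single
    instrument).
    """
    df = _validate(instruments)
    bx = df["beta_x"].to_numpy(float)
    by = df["beta_y"].to_numpy(float)
    w = 1.0 / df["se_y"].to_numpy(float) ** 2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise ValueError("all exposure effects are zero; IVW undefined")
    log_or = float(np.sum(w * bx * by) / denom)
    se = float(1.0 / np.sqrt(denom))
    ci = (float(np.exp(log_or - Z95 * se)), float(np.exp(log_or + Z95 * se)))
    n = len(df)
    q = float(np.sum(w * (by - log_or * bx) ** 2))
    q_p = float(chi2.sf(q, n - 1)) if n > 1 else None
    return MREstimate(log_or, se, ci, n, "ivw", q_stat=q if n > 1 else None, q_p=q_p)


def egger(instruments: pd.DataFrame) -> EggerResult:
    """MR-Egger: weighted regression of beta_y on [1, beta_x], weights 1/se_y^2.

    Requires >= 3 instruments with exposure effects oriented positive (see
    :func:`orient_positive`). Standard errors use the multiplicative
    random-effects convention: the weighted normal-equation SEs scaled by
    max(1, sqrt(residual mean square)); two-sided p-values from the t
    distribution with n - 2 df.
    """
    df = _validate(instruments)
    n = len(df)
    if n < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    bx = df["beta_x"].to_numpy(float)
    by = df["beta_y"].to_numpy(float)
    w = 1.0 / df["se_y"].to_numpy(float) ** 2
    if np.ptp(bx) == 0:
        raise ValueError("all exposure effects are equal; Egger design is rank-deficient")
    X = np.column_stack([np.ones(n), bx])
    XtWX = (X * w[:, None]).T @ X
    coef = np.linalg.solve(XtWX, (X * w[:, None]).T @ by)
    resid = by - X @ coef
    rms = float(np.sum(w * resid**2) / (n - 2))
    scale = max(1.0, np.sqrt(rms))
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov)) * scale
    slope_se = float(se[1])
    tq = float(t_dist.ppf(0.975, n - 2))
    slope_ci = (
        float(np.exp(coef[1] - tq * slope_se)),
        float(np.exp(coef[1] + tq * slope_se)),
    )
    slope = MREstimate(float(coef[1]), slope_se, slope_ci, n, "egger")
    ip = float(2.0 * t_dist.sf(abs(coef[0] / se[0]), n - 2)) if se[0] > 0 else 0.0
    return EggerResult(slope, float(coef[0]), float(se[0]), max(min(ip, 1.0), np.finfo(float).tiny))


def se_from_ci(or_value: float, ci_low: float, ci_high: float) -> float:
    """Reconstruct the log-OR standard error from a printed 95% CI."""
    if not (0 < ci_low < or_value < ci_high):
        raise ValueError("require 0 < ci_low < or_value < ci_high")
    return float((np.log(ci_high) - np.log(ci_low)) / (2.0 * Z95))


def or_difference_test(est1: MREstimate, est2: MREstimate) -> Tuple[float, float]:
    """Difference-of-odds-ratios z test between two MR estimates.

    z = (log OR1 - log OR2) / sqrt(se1^2 + se2^2), two-sided normal p.
    """
    if est1.se <= 0 or est2.se <= 0:
        raise ValueError("both estimates must have positive standard errors")
    z = float((est1.log_or - est2.log_or) / np.hypot(est1.se, est2.se))
    p = float(2.0 * norm.sf(abs(z)))
    return z, p


def instrument_set(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    variant_ids=None,
) -> pd.DataFrame:
    """Join exposure and outcome scans into an instrument table, oriented positive.

    Variants failed in either scan are dropped. The join is on variant_id;
    scans are assumed to share the genotype matrix's effect-allele orientation.
    """
    x = exposure_stats.loc[~exposure_stats["failed"].astype(bool), ["variant_id", "beta", "se"]]
    y = outcome_stats.loc[~outcome_stats["failed"].astype(bool), ["variant_id", "beta", "se"]]
    merged = x.merge(y, on="variant_id", suffixes=("_x", "_y"))
    if variant_ids is not None:
        merged = merged[merged["variant_id"].isin(set(variant_ids))]
    merged = merged.dropna(subset=["beta_x", "se_x", "beta_y", "se_y"]).reset_index(drop=True)
    if len(merged) == 0:
        raise ValueError("no usable instruments after joining scans")
    return orient_positive(merged)
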