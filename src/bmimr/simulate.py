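"""Synthetic cohort generator.

Generates case-control cohorts with the statistical structure the stratified
Mendelian-randomization analysis assumes, so every downstream stage is testable
without access to individual-level biobank data:

* independent instrument genotypes in Hardy-Weinberg equilibrium,
* BMI with an instrument component calibrated to a target in-sample r^2,
* case status from a logistic model with a causal BMI effect theta, a polygenic
  liability effect, and a confounder, intercept calibrated to target prevalence,
* a polygenic risk score (PRS) whose AUC for case status is calibrated by
  noise-variance bisection on a held-out draw,
* family history derived mechanistically from parental/sibling liabilities that
  share half the proband's genetic component plus a shared household
  environment (so family history correlates with both PRS and BMI),
* QC flags, diabetes-type labels and elevated HbA1c among some controls, so
  the exclusion filters have something to catch.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from ._utils import substream
from .config import SimulationConfig

# The 57 BMI instruments used throughout (external GWAS-significant variants
# that pass the missingness/HWE QC thresholds).
INSTRUMENT_RSIDS: Tuple[str, ...] = (
    "rs7899106", "rs17094222", "rs11191560", "rs4256980", "rs2176598",
    "rs3817334", "rs12286929", "rs7138803", "rs11057405", "rs9581854",
    "rs12429545", "rs10132280", "rs12885454", "rs7141420", "rs3736485",
    "rs758747", "rs12446632", "rs2650492", "rs1558902", "rs1000940",
    "rs12940622", "rs1808579", "rs7243357", "rs6567160", "rs17724992",
    "rs29941", "rs2287019", "rs657452", "rs3101336", "rs17024393",
    "rs543874", "rs2820292", "rs13021737", "rs11126666", "rs1016287",
    "rs11688816", "rs2121279", "rs1528435", "rs7599312", "rs6804842",
    "rs3849570", "rs13078960", "rs16851483", "rs1516725", "rs10938397",
    "rs11727676", "rs2112347", "rs2207139", "rs13191362", "rs1167827",
    "rs17405819", "rs2033732", "rs4740619", "rs10968576", "rs6477694",
    "rs1928295", "rs10733682",
)

# The allele-score weight file emulated by the pipeline omits this variant,
# so allele scores are built from the remaining 56 instruments.
SCORE_FILE_MISSING_RSID = "rs9581854"

COHORT_COLUMNS = [
    "id", "bmi", "t2d_case", "family_history", "prs", "age", "sex",
    "genotyping_array", "assessment_center", "hba1c", "metformin", "insulin",
    "qc_exclude", "diabetes_type_label",
]

DIABETES_LABELS = ("t2d_probable", "t2d_possible", "t1_possible", "gestational_possible", "unlikely")


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with optional missingness (NaN)."""

    dosage: np.ndarray  # float (n, m), NaN = missing
    variant_ids: List[str]
    effect_allele: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-dimensional (individuals x variants)")
        if len(self.variant_ids) != self.dosage.shape[1]:
            raise ValueError("variant_ids length must match number of dosage columns")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant_ids must be unique")
        present = self.dosage[~np.isnan(self.dosage)]
        if present.size and (present.min() < 0 or present.max() > 2):
            raise ValueError("dosages must lie within [0, 2] where present")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.variant_ids.index(variant_id)]

    def mean_imputed(self) -> np.ndarray:
        """Dosage matrix with per-variant mean imputation of missing values."""
        d = self.dosage.copy()
        means = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        idx = np.where(np.isnan(d))
        d[idx] = means[idx[1]]
        return d

    def to_dataframe(self, ids=None) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage, columns=self.variant_ids)
        df.insert(0, "id", ids if ids is not None else np.arange(self.n_individuals))
        return df


class CalibrationError(RuntimeError):
    """A generator calibration target could not be met."""


def _bisect_monotone(fn, lo, hi, target, tol, max_steps, target_name, increasing):
    """Bisection for a monotone scalar map; raises CalibrationError on failure."""
    flo, fhi = fn(lo), fn(hi)
    a, b = (flo, fhi) if increasing else (fhi, flo)
    if not (a - tol <= target <= b + tol):
        raise CalibrationError(
            f"cannot calibrate {target_name}: target {target} outside achievable "
            f"range [{min(flo, fhi):.4f}, {max(flo, fhi):.4f}]"
        )
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        fmid = fn(mid)
        if abs(fmid - target) <= tol:
            return mid
        if (fmid < target) == increasing:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(f"bisection for {target_name} did not converge in {max_steps} steps")


def _auc(score: np.ndarray, case: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity."""
    case = np.asarray(case, dtype=bool)
    n1, n0 = case.sum(), (~case).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both cases and controls")
    ranks = rankdata(score)
    return (ranks[case].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _draw_families(rng: np.random.Generator, n: int, cfg: SimulationConfig):
    """Proband genetic liability + family-history flag from parental/sibling liabilities.

    Parents' standardized genetic liabilities are iid N(0,1); the proband and
    one sibling each inherit the mid-parent value plus independent segregation
    noise (so each shares half its genetic component with each parent and with
    the sibling). Relatives' total liability adds a shared household component
    H (which also feeds the proband's BMI) and a non-shared residual; the
    affection threshold is set empirically so that the fraction of probands
    with any affected first-degree relative matches the target.
    """
    h = cfg.fh_heritable_share
    s = cfg.shared_env_liability_share
    zg_m = rng.standard_normal(n)
    zg_f = rng.standard_normal(n)
    mid = 0.5 * (zg_m + zg_f)
    zg = mid + np.sqrt(0.5) * rng.standard_normal(n)
    zg_sib = mid + np.sqrt(0.5) * rng.standard_normal(n)
    household = rng.standard_normal(n)
    resid = np.sqrt(1.0 - h - s)
    liab = np.stack(
        [
            np.sqrt(h) * zg_m + np.sqrt(s) * household + resid * rng.standard_normal(n),
            np.sqrt(h) * zg_f + np.sqrt(s) * household + resid * rng.standard_normal(n),
            np.sqrt(h) * zg_sib + np.sqrt(s) * household + resid * rng.standard_normal(n),
        ]
    )
    worst = liab.max(axis=0)
    threshold = np.quantile(worst, 1.0 - cfg.target_fh_prevalence)
    family_history = worst > threshold
    return zg, household, family_history


def _draw_genotypes(rng: np.random.Generator, n: int, freqs: np.ndarray) -> np.ndarray:
    # binomial(2, f) as the sum of two Bernoulli draws: much faster than
    # rng.binomial with a broadcast p matrix, and exactly HWE by construction
    f = freqs[None, :]
    return (
        (rng.random((n, len(freqs))) < f).astype(float)
        + (rng.random((n, len(freqs))) < f)
    )


def _instrument_component(dosage: np.ndarray, freqs: np.ndarray, target_var: float, raw_beta: np.ndarray):
    """Scale raw instrument effects so the component's in-sample variance hits target_var."""
    centered = dosage - dosage.mean(axis=0)
    raw = centered @ raw_beta
    v = raw.var()
    if v <= 0:
        raise CalibrationError("cannot calibrate target_instrument_r2: instruments carry no variance")
    scale = np.sqrt(target_var / v)
    return raw * scale, raw_beta * scale


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    return _bisect_monotone(
        lambda a: float(expit(a + eta).mean()),
        -40.0, 10.0, target, tol=1e-6, max_steps=100,
        target_name="target_prevalence", increasing=True,
    )


def _draw_phenome(rng: np.random.Generator, n: int, cfg: SimulationConfig, freqs: np.ndarray,
                  raw_beta: np.ndarray):
    """Genotypes, BMI and its components, family history (no case status yet)."""
    dosage = _draw_genotypes(rng, n, freqs)
    genetic_bmi, beta = _instrument_component(
        dosage, freqs, cfg.target_instrument_r2 * cfg.bmi_sd**2, raw_beta
    )
    zg, household, family_history = _draw_families(rng, n, cfg)
    confounder = rng.standard_normal(n)
    resid_var = cfg.bmi_sd**2 * (1.0 - cfg.target_instrument_r2) - (
        cfg.confounder_effect_bmi**2 + cfg.shared_env_bmi_effect**2
    )
    bmi = (
        cfg.bmi_mean
        + genetic_bmi
        + cfg.confounder_effect_bmi * confounder
        + cfg.shared_env_bmi_effect * household
        + np.sqrt(resid_var) * rng.standard_normal(n)
    )
    bmi = np.clip(bmi, 10.5, 79.5)
    return {
        "dosage": dosage,
        "beta": beta,
        "genetic_bmi": genetic_bmi,
        "bmi": bmi,
        "zg": zg,
        "household": household,
        "confounder": confounder,
        "family_history": family_history,
    }


def _case_probabilities(cfg: SimulationConfig, ph: dict, conditional_theta: float):
    """Per-individual case probability with prevalence-calibrated intercept."""
    eta = (
        conditional_theta * (ph["bmi"] - cfg.bmi_mean)
        + cfg.liability_logit_effect * ph["zg"]
        + cfg.confounder_effect_logit * ph["confounder"]
    )
    alpha0 = _calibrate_intercept(eta, cfg.target_prevalence)
    return alpha0, expit(alpha0 + eta)


def _calibrate_generator(cfg: SimulationConfig, freqs: np.ndarray, raw_beta: np.ndarray):
    """Held-out-draw calibration of the two indirect targets.

    Returns (conditional_theta, prs_noise_sd), where

    * ``conditional_theta`` is the BMI coefficient of the conditional logistic
      outcome model chosen so that the *marginal* per-unit-BMI log odds ratio
      -- the estimand of summary MR with a logistic outcome GWAS, which is
      attenuated relative to the conditional coefficient by non-collapsibility
      over the omitted liability/confounder/BMI-residual terms -- equals the
      configured causal_log_or_per_bmi_unit. The marginal effect is measured
      deterministically on the calibration draw as the fractional-logistic
      slope of the expected case probability on the instrument score, divided
      by the control-weighted linear slope of BMI on the score (mirroring the
      control-only exposure GWAS).
    * ``prs_noise_sd`` is the PRS noise level whose AUC for (drawn) case
      status hits the target within ``prs_auc_tolerance``.

    Both use a dedicated random stream so they are not tuned to the delivered
    cohort's realization.
    """
    rng = substream(cfg.seed, 2)
    n_cal = min(max(cfg.n_individuals, 20_000), 50_000)
    ph = _draw_phenome(rng, n_cal, cfg, freqs, raw_beta)
    theta = cfg.causal_log_or_per_bmi_unit
    dosage, bmi = ph["dosage"], ph["bmi"]
    _newton_state: dict = {}

    def marginal_effect(c: float) -> float:
        """Asymptotic per-SNP IVW estimand of the pipeline at conditional slope c.

        Exposure side: control-weighted (1-p) per-SNP linear slope of BMI on
        dosage. Outcome side: per-SNP fractional logistic slope of the expected
        case probability on dosage (a deterministic probability-limit fit).
        Combined with inverse-variance (information) weights, mirroring IVW.
        """
        _, p = _case_probabilities(cfg, ph, c)
        w = 1.0 - p
        sw = w.sum()
        sg = dosage.T @ w
        sgg = (dosage * dosage).T @ w
        sy = float(bmi @ w)
        sgy = dosage.T @ (bmi * w)
        bx = (sw * sgy - sg * sy) / (sw * sgg - sg**2)
        # batched 2-parameter Newton for all variants at once
        # (warm-started from the previous bisection step's solution)
        if "ab" in _newton_state:
            a, b = (v.copy() for v in _newton_state["ab"])
        else:
            a = np.full(dosage.shape[1], np.log(p.mean() / (1.0 - p.mean())))
            b = np.zeros(dosage.shape[1])
        info_b = None
        for _ in range(50):
            mu = expit(a[None, :] + dosage * b[None, :])
            resid = p[:, None] - mu
            ga = resid.sum(axis=0)
            gb = (resid * dosage).sum(axis=0)
            wm = np.clip(mu * (1.0 - mu), 1e-10, None)
            haa = wm.sum(axis=0)
            hab = (wm * dosage).sum(axis=0)
            hbb = (wm * dosage * dosage).sum(axis=0)
            det = haa * hbb - hab**2
            a += (hbb * ga - hab * gb) / det
            b += (haa * gb - hab * ga) / det
            info_b = hbb - hab**2 / haa
            if max(np.abs(ga).max(), np.abs(gb).max()) < 1e-8:
                break
        else:
            raise CalibrationError("marginal-effect calibration: fractional logistic fit failed")
        _newton_state["ab"] = (a, b)
        return float(np.sum(info_b * bx * b) / np.sum(info_b * bx**2))

    if theta == 0.0:
        conditional_theta = 0.0
    else:
        # near-linear map: a one-point pre-estimate gives a tight bracket
        scale0 = theta / marginal_effect(theta)
        lo, hi = sorted((0.85 * scale0 * theta, 1.25 * scale0 * theta))
        conditional_theta = _bisect_monotone(
            marginal_effect, lo, hi, theta, tol=max(1e-3, 2e-3 * abs(theta)),
            max_steps=100, target_name="causal_log_or_per_bmi_unit", increasing=True,
        )

    _, p = _case_probabilities(cfg, ph, conditional_theta)
    case = rng.random(n_cal) < p
    eps = rng.standard_normal(n_cal)
    zg = ph["zg"]

    def auc_at(sd: float) -> float:
        return _auc(zg + sd * eps, case)

    if auc_at(0.0) < cfg.target_prs_auc - cfg.prs_auc_tolerance:
        raise CalibrationError(
            "cannot calibrate target_prs_auc: noiseless genetic liability AUC "
            f"{auc_at(0.0):.3f} is already below the target {cfg.target_prs_auc}"
        )
    prs_noise_sd = _bisect_monotone(
        auc_at, 0.0, 20.0, cfg.target_prs_auc, tol=cfg.prs_auc_tolerance,
        max_steps=100, target_name="target_prs_auc", increasing=False,
    )
    return conditional_theta, prs_noise_sd


def generate_cohort(config: SimulationConfig):
    """Generate (CohortTable, GenotypeMatrix, instrument weights) for a config.

    Returns
    -------
    cohort : pandas.DataFrame
        One row per individual with phenotype, covariate and flag columns
        (see ``COHORT_COLUMNS``; principal components as ``pc1..pcK``).
    genotypes : GenotypeMatrix
        Instrument dosages with injected missingness (one designated "bad"
        variant has elevated missingness so QC filters have something to catch).
    weights : pandas.DataFrame
        Per-variant true instrument effects on BMI: columns
        ``variant_id, effect_allele, beta`` (kg/m^2 per effect-allele dosage).
    """
    cfg = config
    n = cfg.n_individuals
    rng_setup = substream(cfg.seed, 0)
    if cfg.instrument_freqs is not None:
        freqs = np.asarray(list(cfg.instrument_freqs), dtype=float)
    else:
        freqs = rng_setup.uniform(0.05, 0.5, size=cfg.n_instruments)
    # GWAS-like architecture: per-allele effects inversely proportional to the
    # dosage SD, random sign; a single scalar rescales them to the target r^2.
    raw_beta = rng_setup.choice([-1.0, 1.0], size=cfg.n_instruments) / np.sqrt(
        2.0 * freqs * (1.0 - freqs)
    )
    effect_alleles = rng_setup.choice(list("ACGT"), size=cfg.n_instruments).tolist()

    conditional_theta, prs_noise_sd = _calibrate_generator(cfg, freqs, raw_beta)

    rng = substream(cfg.seed, 1)
    draw = _draw_phenome(rng, n, cfg, freqs, raw_beta)
    _, case_p = _case_probabilities(cfg, draw, conditional_theta)
    case = rng.random(n) < case_p
    prs_raw = draw["zg"] + prs_noise_sd * rng.standard_normal(n)
    prs = (prs_raw - prs_raw.mean()) / prs_raw.std()
    n_case = int(case.sum())

    # Diabetes-type labels: cases split probable/possible; a small fraction of
    # controls get non-T2D labels so the exclusion filter is exercised.
    labels = np.where(case, np.where(rng.random(n) < 0.85, "t2d_probable", "t2d_possible"), "unlikely")
    other = (~case) & (rng.random(n) < cfg.other_label_fraction)
    labels = np.where(other, np.where(rng.random(n) < 0.5, "t1_possible", "gestational_possible"), labels)

    # HbA1c (mmol/mol): controls centred at 34 so a few percent exceed the
    # 39 mmol/mol undiagnosed-diabetes threshold; cases clearly elevated.
    hba1c = np.where(case, rng.normal(50.0, 8.0, n), rng.normal(34.0, 3.0, n))
    hba1c = np.clip(hba1c, 5.0, None)

    metformin = case & (rng.random(n) < cfg.case_metformin_rate)
    insulin = case & (rng.random(n) < cfg.case_insulin_rate)
    qc_exclude = rng.random(n) < 0.005

    cohort = pd.DataFrame(
        {
            "id": [f"I{i:07d}" for i in range(n)],
            "bmi": draw["bmi"],
            "t2d_case": case,
            "family_history": draw["family_history"],
            "prs": prs,
            "age": rng.integers(40, 70, n),
            "sex": rng.random(n) < 0.5,
            "genotyping_array": rng.choice(["axiom", "bileve"], n),
            "assessment_center": rng.choice(["center_1", "center_2", "center_3"], n),
            "hba1c": hba1c,
            "metformin": metformin,
            "insulin": insulin,
            "qc_exclude": qc_exclude,
            "diabetes_type_label": labels,
        }
    )
    pcs = rng.standard_normal((n, cfg.n_pcs))
    for k in range(cfg.n_pcs):
        cohort[f"pc{k + 1}"] = pcs[:, k]

    # Inject genotype missingness (dedicated stream; one designated bad variant).
    dosage = draw["dosage"].copy()
    rng_miss = substream(cfg.seed, 3)
    rates = np.full(cfg.n_instruments, cfg.genotype_missing_rate)
    if 0 <= cfg.bad_variant_index < cfg.n_instruments:
        rates[cfg.bad_variant_index] = cfg.bad_variant_missing_rate
    dosage[rng_miss.random(dosage.shape) < rates[None, :]] = np.nan

    if cfg.n_instruments == len(INSTRUMENT_RSIDS):
        variant_ids = list(INSTRUMENT_RSIDS)
    else:
        variant_ids = [f"rsSYN{j:04d}" for j in range(cfg.n_instruments)]
    genotypes = GenotypeMatrix(dosage, variant_ids, effect_alleles)
    weights = pd.DataFrame(
        {"variant_id": variant_ids, "effect_allele": effect_alleles, "beta": draw["beta"]}
    )
    if n_case == 0 or n_case == n:
        raise CalibrationError("degenerate cohort: all individuals share one case status")
    return cohort, genotypes, weights


def apply_exclusions(cohort: pd.DataFrame):
    """QC and phenotype exclusions applied before any analysis.

    Removes, in order of precedence (each row counted once):

    1. rows flagged ``qc_exclude`` (sample QC failures),
    2. rows labelled possible type 1 or gestational diabetes,
    3. controls with HbA1c >= 39 mmol/mol (undiagnosed diabetes / prediabetes).

    Cases are never excluded on HbA1c. Returns the filtered table and a
    per-reason count dict ``{"qc": ..., "type": ..., "hba1c": ...}``.
    Idempotent: re-applying to the output removes nothing.
    """
    for col in ("hba1c", "qc_exclude", "diabetes_type_label", "t2d_case"):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing required column '{col}'")
    qc = cohort["qc_exclude"].astype(bool)
    typ = cohort["diabetes_type_label"].isin(["t1_possible", "gestational_possible"]) & ~qc
    hba = (~cohort["t2d_case"].astype(bool)) & (cohort["hba1c"] >= 39.0) & ~qc & ~typ
    counts = {"qc": int(qc.sum()), "type": int(typ.sum()), "hba1c": int(hba.sum())}
    kept = cohort.loc[~(qc | typ | hba)].reset_index(drop=True)
    if len(kept) == 0:
        warnings.warn("apply_exclusions removed every row", stacklevel=2)
    return kept, counts
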