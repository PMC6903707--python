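"""End-to-end analysis orchestration.

``run_analysis`` wires the stages together: obtain a cohort (simulate or load
files), apply exclusions, guard the stratifying variables against collider
bias, tabulate stratified prevalence, run per-stratum instrument scans and
IVW / MR-Egger estimation, nonlinear (quantile) MR on the full cohort, and
risk-translation tables. Outputs are deterministic given the configuration
and seed; a JSON manifest records the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .assoc import design_from_cohort, filter_instruments, linear_assoc, logistic_assoc
from .collider import match_binary, residualize
from .config import AnalysisConfig
from .io import (
    read_cohort,
    read_genotypes_tsv,
    read_weights,
    write_cohort,
    write_genotypes_tsv,
    write_summary_stats,
    write_weights,
)
from .mr import MREstimate, egger, instrument_set, ivw
from .nonlinear import allele_score, quantile_mr
from .risk import (
    absolute_risk_reduction,
    prevalence_after,
    propagate_ci,
    relative_risk_reduction,
    render_percent,
    render_weight,
    weight_for_absolute_reduction,
    weight_for_relative_reduction,
)
from .simulate import SCORE_FILE_MISSING_RSID, GenotypeMatrix, apply_exclusions, generate_cohort
from .strata import BMI_CATEGORIES, PRS_TERTILES, assign_strata, binned_prevalence, prevalence_table

log = logging.getLogger("bmimr")


def _subset(genotypes: GenotypeMatrix, rows: np.ndarray) -> GenotypeMatrix:
    return GenotypeMatrix(genotypes.dosage[rows], genotypes.variant_ids, genotypes.effect_allele)


def _mr_row(name: str, cohort: pd.DataFrame, genotypes: GenotypeMatrix,
            covariates: pd.DataFrame, kept_ids: List[str]) -> Dict[str, object]:
    """IVW + Egger for one stratum; NA row (with reason) on degenerate input."""
    case = cohort["t2d_case"].astype(bool).to_numpy()
    na = {
        "stratum": name, "n": len(cohort), "n_cases": int(case.sum()),
        "n_instruments": 0, "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
        "q_stat": np.nan, "q_p": np.nan, "egger_or": np.nan,
        "egger_intercept": np.nan, "egger_intercept_p": np.nan, "note": "",
    }
    if case.sum() == 0 or (~case).sum() == 0:
        na["note"] = "no cases in stratum" if case.sum() == 0 else "no controls in stratum"
        log.warning("stratum %s skipped: %s", name, na["note"])
        return na
    controls = np.flatnonzero(~case)
    try:
        exp_stats = linear_assoc(
            _subset(genotypes, controls),
            cohort["bmi"].to_numpy(float)[controls],
            covariates.iloc[controls],
        )
        out_stats = logistic_assoc(genotypes, case, covariates)
        inst = instrument_set(exp_stats, out_stats, kept_ids)
        est = ivw(inst)
        row = dict(na)
        row.update(
            n_instruments=est.n_instruments, **{"or": est.odds_ratio},
            ci_low=est.ci95[0], ci_high=est.ci95[1],
            q_stat=est.q_stat if est.q_stat is not None else np.nan,
            q_p=est.q_p if est.q_p is not None else np.nan,
        )
        if len(inst) >= 3:
            eg = egger(inst)
            row.update(
                egger_or=eg.slope.odds_ratio,
                egger_intercept=eg.intercept,
                egger_intercept_p=eg.intercept_p,
            )
        return row
    except (ValueError, RuntimeError) as exc:
        na["note"] = f"MR failed: {exc}"
        log.warning("stratum %s: %s", name, na["note"])
        return na


def _risk_tables(estimates: Dict[str, MREstimate], prevalences: Dict[str, float],
                 height_m: float = 1.7) -> Dict[str, pd.DataFrame]:
    """Risk-translation analogues of the published calculator tables."""
    cats = [c for c in BMI_CATEGORIES if c in estimates]
    rows3 = []
    for cat in cats:
        est, P = estimates[cat], prevalences[cat]
        beta, ci = est.odds_ratio, est.ci95
        after = prevalence_after(P, beta, 1.0)
        after_ci = propagate_ci(lambda b: prevalence_after(P, b, 1.0), ci)
        arr = absolute_risk_reduction(P, beta, 1.0)
        arr_ci = propagate_ci(lambda b: absolute_risk_reduction(P, b, 1.0), ci)
        rows3.append({
            "bmi_category": cat, "odds_ratio": beta,
            "or_ci_low": ci[0], "or_ci_high": ci[1], "prevalence": P,
            "prevalence_after_1unit": after,
            "prevalence_after_rendered": f"{render_percent(after, 1)} ({render_percent(after_ci[0], 1)}, {render_percent(after_ci[1], 1)})",
            "absolute_reduction_1unit": arr,
            "absolute_reduction_rendered": f"{render_percent(arr, 1)} ({render_percent(arr_ci[0], 1)}, {render_percent(arr_ci[1], 1)})",
        })
    rows4, rows5 = [], []
    for kg in (2.3, 4.5, 5.0, 9.1, 10.0):
        delta = kg / height_m**2
        rec = {"weight_lost_kg": kg}
        for cat in cats:
            if estimates[cat].odds_ratio <= 1:
                continue
            beta, ci = estimates[cat].odds_ratio, estimates[cat].ci95
            rel = relative_risk_reduction(beta, delta)
            rel_ci = propagate_ci(lambda b: relative_risk_reduction(b, delta), ci)
            rec[f"relative_{cat}"] = (
                f"{render_percent(rel)} ({render_percent(rel_ci[0])}, {render_percent(rel_ci[1])})"
            )
        rows4.append(rec)
    for label, kind, target in (
        ("25%, relative", "rel", 0.25), ("50%, relative", "rel", 0.50),
        ("1%, absolute", "abs", 0.01), ("2%, absolute", "abs", 0.02),
    ):
        rec = {"reduction": label}
        for cat in cats:
            est, P = estimates[cat], prevalences[cat]
            if est.odds_ratio <= 1 or (kind == "abs" and target >= P):
                rec[cat] = "NA"
                continue
            if kind == "rel":
                op = lambda b: weight_for_relative_reduction(b, target, height_m)
            else:
                op = lambda b: weight_for_absolute_reduction(P, b, target, height_m)
            kg, _ = op(est.odds_ratio)
            try:
                (kg_lo, _), (kg_hi, _) = propagate_ci(op, est.ci95)
                rec[cat] = f"{render_weight(kg)} ({render_weight(kg_lo)}, {render_weight(kg_hi)})"
            except ValueError:
                rec[cat] = f"{render_weight(kg)} (CI undefined: bound OR <= 1)"
        rows5.append(rec)
    return {
        "risk_table3": pd.DataFrame(rows3),
        "risk_table4": pd.DataFrame(rows4),
        "risk_table5": pd.DataFrame(rows5),
    }


def run_analysis(config: AnalysisConfig) -> Dict[str, object]:
    """Execute the full pipeline; returns the result bundle and writes outputs."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    stage = "setup"

    def _emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        written.append(path)

    try:
        stage = "input"
        if config.mode == "simulate":
            cohort, genotypes, weights = generate_cohort(config.simulation)
            # the emulated external score-weight file omits one instrument
            score_weights = weights[weights["variant_id"] != SCORE_FILE_MISSING_RSID].reset_index(drop=True)
            _emit("cohort.tsv", lambda p: write_cohort(cohort, p))
            _emit("genotypes.tsv", lambda p: write_genotypes_tsv(genotypes, p, cohort["id"]))
            _emit("score_weights.tsv", lambda p: write_weights(score_weights, p))
        else:
            cohort = read_cohort(config.cohort_path)
            genotypes = read_genotypes_tsv(config.genotypes_path)
            weights = read_weights(config.weights_path)
            score_weights = weights
        log.info("stage %-12s %6.1fs  n=%d, m=%d", stage, time.time() - t0, len(cohort), genotypes.n_variants)

        stage = "exclusions"
        cohort["_row"] = np.arange(len(cohort))
        cohort, exclusion_counts = apply_exclusions(cohort)
        genotypes = _subset(genotypes, cohort["_row"].to_numpy())
        cohort = cohort.drop(columns="_row").reset_index(drop=True)
        log.info("stage %-12s %6.1fs  kept=%d  %s", stage, time.time() - t0, len(cohort), exclusion_counts)

        stage = "instrument_qc"
        covariates = design_from_cohort(cohort)
        case = cohort["t2d_case"].astype(bool).to_numpy()
        controls = np.flatnonzero(~case)
        exposure_stats = linear_assoc(
            _subset(genotypes, controls), cohort["bmi"].to_numpy(float)[controls],
            covariates.iloc[controls],
        )
        kept_ids, qc_reasons = filter_instruments(
            exposure_stats, config.max_missing, config.min_hwe_midp, genotypes.variant_ids
        )
        _emit("exposure_stats_full.tsv", lambda p: write_summary_stats(exposure_stats, p))
        log.info("stage %-12s %6.1fs  instruments kept=%d dropped=%d",
                 stage, time.time() - t0, len(kept_ids), len(qc_reasons))

        stage = "collider_guard"
        adj_bmi = residualize(cohort["bmi"].to_numpy(float), genotypes, kept_ids)
        adj_prs = residualize(cohort["prs"].to_numpy(float), genotypes, kept_ids)
        labels = assign_strata(cohort, adj_bmi, adj_prs)
        matched_rows, match_report = match_binary(
            cohort["family_history"].astype(bool).to_numpy(), genotypes, kept_ids,
            ratio=config.match_ratio, n_bins=config.match_bins, seed=config.seed,
        )
        log.info("stage %-12s %6.1fs  matched kept=%d excluded=%d", stage, time.time() - t0,
                 match_report.n_exposed_kept + match_report.n_unexposed_kept, match_report.n_excluded)

        stage = "prevalence"
        fh_lab = np.where(labels["family_history"], "yes", "no")
        overall = prevalence_table(case, ["overall"] * len(cohort), labels["bmi_category"],
                                   "overall", "bmi", ["overall"], list(BMI_CATEGORIES))
        by_fh = prevalence_table(case, fh_lab, labels["bmi_category"],
                                 "family_history", "bmi", ["no", "yes"], list(BMI_CATEGORIES))
        by_prs = prevalence_table(case, labels["prs_tertile"], labels["bmi_category"],
                                  "prs_tertile", "bmi", list(PRS_TERTILES), list(BMI_CATEGORIES))
        curves = binned_prevalence(adj_bmi, case, fh_lab, n_bins=min(50, len(cohort) // 40 or 1))
        for tag, tab in (("overall", overall), ("family_history", by_fh), ("prs", by_prs)):
            _emit(f"prevalence_{tag}.tsv", lambda p, t=tab: t.data.to_csv(p, sep="\t", index=False))
            _emit(f"prevalence_{tag}.txt", lambda p, t=tab: Path(p).write_text(t.render() + "\n"))
        _emit("prevalence_curves.tsv", lambda p: curves.to_csv(p, sep="\t", index=False))

        stage = "stratified_mr"
        strata_masks = []
        if "overall" in config.stratifications or "bmi" in config.stratifications:
            strata_masks.append(("overall|all", np.ones(len(cohort), bool)))
        for what in config.stratifications:
            if what == "bmi":
                for cat in BMI_CATEGORIES:
                    strata_masks.append((f"overall|{cat}", (labels["bmi_category"] == cat).to_numpy()))
            elif what == "prs_tertile":
                for ter in PRS_TERTILES:
                    strata_masks.append((f"prs_{ter}|all", (labels["prs_tertile"] == ter).to_numpy()))
            elif what == "medication":
                from .strata import medication_stratum_mask
                for med in ("metformin_only", "insulin_only"):
                    strata_masks.append((f"{med}|all", medication_stratum_mask(cohort, med)))
        mr_rows = []
        for name, mask in strata_masks:
            rows = np.flatnonzero(mask)
            mr_rows.append(_mr_row(name, cohort.iloc[rows].reset_index(drop=True),
                                   _subset(genotypes, rows), covariates.iloc[rows].reset_index(drop=True),
                                   kept_ids))
        if "family_history" in config.stratifications:
            msub = cohort.iloc[matched_rows].reset_index(drop=True)
            mcov = covariates.iloc[matched_rows].reset_index(drop=True)
            mgen = _subset(genotypes, matched_rows)
            mfh = labels["family_history"].to_numpy()[matched_rows]
            for val, tag in ((False, "fh_no"), (True, "fh_yes")):
                rows = np.flatnonzero(mfh == val)
                mr_rows.append(_mr_row(f"{tag}|all", msub.iloc[rows].reset_index(drop=True),
                                       _subset(mgen, rows), mcov.iloc[rows].reset_index(drop=True),
                                       kept_ids))
        mr_results = pd.DataFrame(mr_rows)
        _emit("mr_results.tsv", lambda p: mr_results.to_csv(p, sep="\t", index=False, na_rep="NA"))
        log.info("stage %-12s %6.1fs  strata=%d", stage, time.time() - t0, len(mr_results))

        stage = "nonlinear_mr"
        nonlinear = None
        if len(cohort) >= 20 * config.n_quantiles:
            score = allele_score(genotypes, score_weights)
            try:
                nonlinear = quantile_mr(cohort["bmi"].to_numpy(float), case, score,
                                        covariates, config.n_quantiles)
            except RuntimeError as exc:
                # every stratum degenerate (tiny cohorts): degraded, not fatal
                log.warning("nonlinear MR skipped: %s", exc)
            else:
                _emit("quantile_mr.tsv",
                      lambda p: nonlinear.per_quantile.to_csv(p, sep="\t", index=False))
        else:
            log.warning("cohort too small for %d-quantile MR; stage skipped", config.n_quantiles)

        stage = "risk_translation"
        estimates, prevalences = {}, {}
        for cat in BMI_CATEGORIES:
            row = mr_results[mr_results["stratum"] == f"overall|{cat}"]
            sel = (labels["bmi_category"] == cat).to_numpy()
            if len(row) == 1 and np.isfinite(row["or"].iloc[0]) and sel.sum() > 0 and case[sel].mean() > 0:
                r = row.iloc[0]
                estimates[cat] = MREstimate(
                    float(np.log(r["or"])), float((np.log(r["ci_high"]) - np.log(r["ci_low"])) / (2 * 1.96)),
                    (float(r["ci_low"]), float(r["ci_high"])), int(r["n_instruments"]), "ivw",
                )
                prevalences[cat] = float(case[sel].mean())
        risk_tables = _risk_tables(estimates, prevalences) if estimates else {}
        for name, tab in risk_tables.items():
            _emit(f"{name}.tsv", lambda p, t=tab: t.to_csv(p, sep="\t", index=False))

        stage = "manifest"
        cfg_desc = {
            "mode": config.mode, "seed": config.seed,
            "max_missing": config.max_missing, "min_hwe_midp": config.min_hwe_midp,
            "n_quantiles": config.n_quantiles, "match_ratio": config.match_ratio,
            "stratifications": list(config.stratifications),
            "simulation": json.loads(config.simulation.to_json()) if config.simulation else None,
            "paths": {"cohort": config.cohort_path, "genotypes": config.genotypes_path,
                      "weights": config.weights_path},
        }
        manifest = {
            "config": cfg_desc,
            "config_hash": hashlib.sha256(json.dumps(cfg_desc, sort_keys=True).encode()).hexdigest(),
            "seed": config.seed,
            "versions": {"bmimr": __version__, "numpy": np.__version__, "pandas": pd.__version__,
                         "python": sys.version.split()[0]},
            "exclusion_counts": exclusion_counts,
            "n_analyzed": int(len(cohort)),
            "instruments_kept": kept_ids,
            "instrument_qc_rejections": qc_reasons,
            "match_report": {
                "n_exposed_kept": match_report.n_exposed_kept,
                "n_unexposed_kept": match_report.n_unexposed_kept,
                "n_excluded": match_report.n_excluded,
                "shortfall_bins": match_report.shortfall_bins,
            },
        }
        _emit("manifest.json", lambda p: Path(p).write_text(json.dumps(manifest, indent=2) + "\n"))
        log.info("run complete in %.1fs -> %s", time.time() - t0, outdir)
        return {
            "cohort": cohort, "genotypes": genotypes, "weights": weights,
            "exclusion_counts": exclusion_counts, "labels": labels,
            "adjusted_bmi": adj_bmi, "adjusted_prs": adj_prs,
            "prevalence_tables": {"overall": overall, "family_history": by_fh, "prs": by_prs},
            "prevalence_curves": curves, "mr_results": mr_results,
            "nonlinear": nonlinear, "risk_tables": risk_tables,
            "match_report": match_report, "manifest": manifest,
        }
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
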