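"""Apply the QC/phenotype exclusions and tabulate stratified prevalence.

Reads the cohort written by 01_simulate_cohort.py (regenerating it if
absent), applies the sample exclusions (QC flags, type 1 / gestational
labels, controls with HbA1c >= 39 mmol/mol), computes collider-adjusted BMI
and polygenic score, and writes the stratified prevalence / relative-risk
tables plus the 50-bin prevalence curves under results/.
"""

from pathlib import Path

import numpy as np

from bmimr import apply_exclusions, prevalence_table, residualize, binned_prevalence
from bmimr.io import read_cohort, read_genotypes_tsv
from bmimr.pipeline import _subset
from bmimr.strata import BMI_CATEGORIES, PRS_TERTILES, assign_strata

ROOT = Path(__file__).resolve().parents[1]


def load_cohort():
    data = ROOT / "scratch" / "data"
    if not (data / "cohort.tsv").exists():
        import subprocess, sys

        subprocess.run([sys.executable, str(ROOT / "analysis" / "01_simulate_cohort.py")], check=True)
    return read_cohort(data / "cohort.tsv"), read_genotypes_tsv(data / "genotypes.tsv")


def main() -> None:
    cohort, genotypes = load_cohort()
    cohort["_row"] = np.arange(len(cohort))
    cohort, counts = apply_exclusions(cohort)
    genotypes = _subset(genotypes, cohort["_row"].to_numpy())
    cohort = cohort.drop(columns="_row").reset_index(drop=True)
    print(f"exclusions: {counts}; analyzed cohort n={len(cohort)}")

    adj_bmi = residualize(cohort["bmi"].to_numpy(), genotypes)
    adj_prs = residualize(cohort["prs"].to_numpy(), genotypes)
    labels = assign_strata(cohort, adj_bmi, adj_prs)
    case = cohort["t2d_case"].to_numpy(bool)
    fh = np.where(labels["family_history"], "yes", "no")

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    tables = {
        "overall": prevalence_table(case, ["overall"] * len(cohort), labels["bmi_category"],
                                    "overall", "bmi", ["overall"], list(BMI_CATEGORIES)),
        "family_history": prevalence_table(case, fh, labels["bmi_category"],
                                           "family_history", "bmi", ["no", "yes"],
                                           list(BMI_CATEGORIES)),
        "prs": prevalence_table(case, labels["prs_tertile"], labels["bmi_category"],
                                "prs_tertile", "bmi", list(PRS_TERTILES), list(BMI_CATEGORIES)),
    }
    for tag, tab in tables.items():
        tab.data.to_csv(out / f"prevalence_{tag}.tsv", sep="\t", index=False)
        (out / f"prevalence_{tag}.txt").write_text(tab.render() + "\n")
        print(f"\n== prevalence by {tag} x BMI category ==")
        print(tab.render())

    curves = binned_prevalence(adj_bmi, case, fh, n_bins=50)
    curves.to_csv(out / "prevalence_curves_fh.tsv", sep="\t", index=False)
    print(f"\n50-bin prevalence curves -> {out / 'prevalence_curves_fh.tsv'}")


if __name__ == "__main__":
    main()
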