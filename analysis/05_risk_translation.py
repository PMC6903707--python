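"""Risk-translation calculator tables from the published MR odds ratios.

These tables are pure closed-form arithmetic on printed inputs: the per-BMI-
category MR odds ratios (non-overweight 1.31 [1.11-1.53], overweight 1.36
[1.28-1.45], obese 1.25 [1.20-1.31]) and Public Health England prevalences
(2.4% / 5.2% / 12.4%). They answer, for a 1.7-m-tall individual: how much
does a given weight loss reduce diabetes risk, and how much weight loss buys
a given risk reduction.
"""

from pathlib import Path

import pandas as pd

from bmimr import (
    absolute_risk_reduction,
    prevalence_after,
    propagate_ci,
    relative_risk_reduction,
    render_percent,
    render_weight,
    weight_for_absolute_reduction,
    weight_for_relative_reduction,
)

ROOT = Path(__file__).resolve().parents[1]
H = 1.7

CATEGORIES = {
    "non_overweight": {"or": 1.31, "ci": (1.11, 1.53), "prevalence": 0.024},
    "overweight": {"or": 1.36, "ci": (1.28, 1.45), "prevalence": 0.052},
    "obese": {"or": 1.25, "ci": (1.20, 1.31), "prevalence": 0.124},
}


def table3():
    rows = []
    for cat, d in CATEGORIES.items():
        beta, ci, P = d["or"], d["ci"], d["prevalence"]
        after = prevalence_after(P, beta, 1.0)
        a_lo, a_hi = propagate_ci(lambda b: prevalence_after(P, b, 1.0), ci)
        arr = absolute_risk_reduction(P, beta, 1.0)
        r_lo, r_hi = propagate_ci(lambda b: absolute_risk_reduction(P, b, 1.0), ci)
        rows.append(
            {
                "bmi_category": cat,
                "odds_ratio": f"{beta} ({ci[0]}, {ci[1]})",
                "prevalence": render_percent(P, 1),
                "prevalence_after_1unit": f"{render_percent(after, 1)} ({render_percent(a_lo, 1)}, {render_percent(a_hi, 1)})",
                "absolute_reduction": f"{render_percent(arr, 1)} ({render_percent(r_lo, 1)}, {render_percent(r_hi, 1)})",
            }
        )
    return pd.DataFrame(rows)


def table4():
    rows = []
    for kg in (2.3, 4.5, 5.0, 9.1, 10.0):
        delta = kg / H**2
        row = {"weight_lost_kg": kg}
        for cat in ("overweight", "obese"):
            beta, ci = CATEGORIES[cat]["or"], CATEGORIES[cat]["ci"]
            rel = relative_risk_reduction(beta, delta)
            lo, hi = propagate_ci(lambda b: relative_risk_reduction(b, delta), ci)
            row[f"relative_{cat}"] = f"{render_percent(rel)} ({render_percent(lo)}, {render_percent(hi)})"
        rows.append(row)
    return pd.DataFrame(rows)


def table5():
    rows = []
    specs = [("25%, relative", "rel", 0.25), ("50%, relative", "rel", 0.50),
             ("1%, absolute", "abs", 0.01), ("2%, absolute", "abs", 0.02)]
    for label, kind, target in specs:
        row = {"reduction": label}
        for cat in ("overweight", "obese"):
            beta, ci, P = (CATEGORIES[cat][k] for k in ("or", "ci", "prevalence"))
            if kind == "rel":
                op = lambda b: weight_for_relative_reduction(b, target, H)
            else:
                op = lambda b: weight_for_absolute_reduction(P, b, target, H)
            kg, _ = op(beta)
            (kg_lo, _), (kg_hi, _) = propagate_ci(op, ci)
            row[cat] = f"{render_weight(kg)} ({render_weight(kg_lo)}, {render_weight(kg_hi)})"
        rows.append(row)
    return pd.DataFrame(rows)


def main() -> None:
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    for name, tab in (("published_table3", table3()), ("published_table4", table4()),
                      ("published_table5", table5())):
        tab.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        print(f"== {name} ==")
        print(tab.to_string(index=False))
        print()
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
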