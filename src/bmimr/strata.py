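"""Stratum definitions, stratified prevalence/relative-risk tables, and
binned prevalence curves.

BMI categories use half-open intervals [-inf, 25), [25, 30), [30, inf) kg/m^2;
polygenic-score tertiles are empirical equal-size thirds of the
instrument-adjusted score within the analyzed cohort; medication strata keep
cases prescribed exactly one drug plus all controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import bin_by_rank, equal_bin_sizes, round_half_away

BMI_CATEGORIES = ("non_overweight", "overweight", "obese")
PRS_TERTILES = ("low", "medium", "high")


def bmi_category(bmi) -> pd.Categorical:
    """'non_overweight' [<25), 'overweight' [25,30), 'obese' [30,inf)."""
    b = np.asarray(bmi, dtype=float)
    labels = np.where(b < 25.0, "non_overweight", np.where(b < 30.0, "overweight", "obese"))
    return pd.Categorical(labels, categories=list(BMI_CATEGORIES), ordered=True)


def prs_tertile(adjusted_prs) -> pd.Categorical:
    """Empirical tertiles (low/medium/high) of the adjusted polygenic score.

    Rank-based with stable tie-breaking so tertile sizes differ by <= 1.
    """
    bins = bin_by_rank(np.asarray(adjusted_prs, dtype=float), 3)
    return pd.Categorical(
        np.array(PRS_TERTILES, dtype=object)[bins], categories=list(PRS_TERTILES), ordered=True
    )


def medication_stratum_mask(cohort: pd.DataFrame, which: str) -> np.ndarray:
    """Rows for a case-medication stratum: cases on exactly that drug + all controls."""
    case = cohort["t2d_case"].astype(bool).to_numpy()
    met = cohort["metformin"].astype(bool).to_numpy()
    ins = cohort["insulin"].astype(bool).to_numpy()
    if which == "metformin_only":
        keep_case = case & met & ~ins
    elif which == "insulin_only":
        keep_case = case & ins & ~met
    else:
        raise ValueError("which must be 'metformin_only' or 'insulin_only'")
    return keep_case | ~case


def assign_strata(
    cohort: pd.DataFrame,
    adjusted_bmi,
    adjusted_prs,
) -> pd.DataFrame:
    """Per-individual stratum labels from the collider-adjusted variables."""
    if len(adjusted_bmi) != len(cohort) or len(adjusted_prs) != len(cohort):
        raise ValueError("adjusted vectors must align with the cohort")
    return pd.DataFrame(
        {
            "bmi_category": bmi_category(adjusted_bmi),
            "family_history": cohort["family_history"].astype(bool).to_numpy(),
            "prs_tertile": prs_tertile(adjusted_prs),
        },
        index=cohort.index,
    )


@dataclass
class PrevalenceTable:
    """Per-cell counts, prevalence and relative risk vs the top-left cell."""

    data: pd.DataFrame  # row_label, col_label, n, n_cases, prevalence, relative_risk
    row_factor: str
    col_factor: str

    def render(self) -> str:
        """Rendered table: prevalence to 1 decimal %, RR to 1 decimal x.

        The rendered TSV keeps n and n_cases so parsing it recovers the
        counts exactly.
        """
        lines = ["\t".join([self.row_factor + "\\" + self.col_factor, "n", "n_cases", "prevalence", "relative_risk"])]
        for row in self.data.itertuples(index=False):
            if row.n == 0:
                prev_s, rr_s = "—", "—"
            else:
                prev_s = f"{round_half_away(100.0 * row.prevalence, 1):.1f}%"
                rr_s = (
                    f"{round_half_away(row.relative_risk, 1):.1f}×"
                    if np.isfinite(row.relative_risk)
                    else "—"
                )
            lines.append(
                "\t".join(
                    [f"{row.row_label}|{row.col_label}", str(row.n), str(row.n_cases), prev_s, rr_s]
                )
            )
        return "\n".join(lines)


def prevalence_table(
    case,
    row_labels,
    col_labels,
    row_factor: str = "row",
    col_factor: str = "col",
    row_order: Optional[Sequence] = None,
    col_order: Optional[Sequence] = None,
) -> PrevalenceTable:
    """Cross-tabulated prevalence with relative risks vs the top-left cell.

    The reference cell is the first row category x first column category; its
    relative risk is 1 by construction. Empty cells get undefined prevalence.
    """
    case = np.asarray(case, dtype=bool)
    rows = pd.Series(row_labels)
    cols = pd.Series(col_labels)
    r_order = list(row_order) if row_order is not None else list(pd.unique(rows))
    c_order = list(col_order) if col_order is not None else list(pd.unique(cols))
    records = []
    ref_prev = None
    for r in r_order:
        for c in c_order:
            sel = (rows == r).to_numpy() & (cols == c).to_numpy()
            n = int(sel.sum())
            n_cases = int(case[sel].sum())
            prev = n_cases / n if n > 0 else np.nan
            records.append([r, c, n, n_cases, prev])
            if ref_prev is None:
                ref_prev = prev
    df = pd.DataFrame(records, columns=["row_label", "col_label", "n", "n_cases", "prevalence"])
    if ref_prev and ref_prev > 0:
        df["relative_risk"] = df["prevalence"] / ref_prev
    else:
        df["relative_risk"] = np.where(np.arange(len(df)) == 0, 1.0, np.nan)
    return PrevalenceTable(df, row_factor, col_factor)


def binned_prevalence(
    bmi,
    case,
    groups=None,
    n_bins: int = 50,
) -> pd.DataFrame:
    """Per-group equal-count BMI bins with mean BMI and case fraction.

    Within each group, individuals are sorted by BMI (stable) and split into
    ``n_bins`` contiguous bins whose sizes differ by at most one (the larger
    bins take the highest BMI values). Returns a tidy frame ordered by group
    then bin mean BMI.
    """
    bmi = np.asarray(bmi, dtype=float)
    case = np.asarray(case, dtype=bool)
    if groups is None:
        groups = np.zeros(len(bmi), dtype=int)
    groups = np.asarray(groups)
    records = []
    for g in pd.unique(groups):
        sel = groups == g
        n = int(sel.sum())
        if n < n_bins:
            raise ValueError(
                f"group {g!r} has {n} individuals, fewer than {n_bins} bins; use fewer bins"
            )
        order = np.argsort(bmi[sel], kind="stable")
        b_sorted = bmi[sel][order]
        c_sorted = case[sel][order]
        sizes = equal_bin_sizes(n, n_bins)
        start = 0
        for k, size in enumerate(sizes):
            stop = start + size
            records.append([g, k, size, float(b_sorted[start:stop].mean()),
                            float(c_sorted[start:stop].mean())])
            start = stop
    return pd.DataFrame(records, columns=["group", "bin", "n", "mean_bmi", "prevalence"])
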