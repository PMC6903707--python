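"""Reading and writing the pipeline's tabular formats.

All formats are plain text: the cohort table and summary statistics as TSV
with fixed headers (booleans as 0/1, missing as "NA"), the genotype dosage
matrix as a TSV (rows = individuals, columns = variant ids) or a minimal VCF
with a DS FORMAT field, and instrument weights as a 3-column TSV. Readers
validate headers strictly and report malformed values with row/column
coordinates; write-then-read round-trips to the canonical in-memory form.
"""

from __future__ import annotations

import warnings
from typing import List, Optional

import numpy as np
import pandas as pd

from .simulate import COHORT_COLUMNS, DIABETES_LABELS, GenotypeMatrix

_BOOL_COLUMNS = ["t2d_case", "family_history", "sex", "metformin", "insulin", "qc_exclude"]
_FLOAT_COLUMNS = ["bmi", "prs", "hba1c"]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    df = cohort.copy()
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(bool).astype(int)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, dtype={"id": str})
    pc_cols = [c for c in df.columns if c.startswith("pc") and c[2:].isdigit()]
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing mandatory columns: {missing}")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS and c not in pc_cols]
    if unknown:
        warnings.warn(f"cohort file {path} has unknown columns (kept): {unknown}", stacklevel=2)
    for col in _BOOL_COLUMNS:
        bad = ~df[col].isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"cohort file {path}: non-0/1 value in column '{col}', data row {row + 1}")
        df[col] = df[col].astype(bool)
    for col in _FLOAT_COLUMNS:
        df[col] = df[col].astype(float)
    df["age"] = df["age"].astype(int)
    bad_label = ~df["diabetes_type_label"].isin(DIABETES_LABELS)
    if bad_label.any():
        row = int(np.flatnonzero(bad_label.to_numpy())[0])
        raise ValueError(
            f"cohort file {path}: unknown diabetes_type_label "
            f"'{df['diabetes_type_label'].iloc[row]}' at data row {row + 1}"
        )
    return df[COHORT_COLUMNS + sorted(pc_cols, key=lambda c: int(c[2:]))]


def write_genotypes_tsv(genotypes: GenotypeMatrix, path, ids=None) -> None:
    genotypes.to_dataframe(ids).to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_genotypes_tsv(path, effect_alleles: Optional[List[str]] = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, dtype={"id": str})
    if df.columns[0] != "id":
        raise ValueError(f"genotype file {path}: first column must be 'id'")
    variant_ids = list(df.columns[1:])
    try:
        dosage = df[variant_ids].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"genotype file {path}: non-numeric dosage value ({exc})") from exc
    bad = (dosage < 0) | (dosage > 2)
    if np.any(bad & ~np.isnan(dosage)):
        i, j = map(int, np.argwhere(bad & ~np.isnan(dosage))[0])
        raise ValueError(
            f"genotype file {path}: dosage {dosage[i, j]} out of [0, 2] at data row "
            f"{i + 1}, variant '{variant_ids[j]}'"
        )
    return GenotypeMatrix(dosage, variant_ids, effect_alleles)


def write_weights(weights: pd.DataFrame, path) -> None:
    weights[["variant_id", "effect_allele", "beta"]].to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["variant_id", "effect_allele", "beta"]
    if list(df.columns) != expected:
        raise ValueError(f"weights file {path}: header must be {expected}, got {list(df.columns)}")
    df["beta"] = df["beta"].astype(float)
    return df


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    df["failed"] = df["failed"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Minimal VCF support (dosages in the DS FORMAT field)


def write_vcf(genotypes: GenotypeMatrix, path, ids=None) -> None:
    """Write dosages as a minimal VCF 4.2 with a DS FORMAT field.

    Variants are placed on a synthetic contig at consecutive positions; the
    effect allele is written as ALT (REF fixed to the complementary label 'N'
    is not legal VCF, so REF/ALT use A/effect allele or G when they collide).
    """
    n = genotypes.n_individuals
    sample_ids = list(ids) if ids is not None else [f"I{i:07d}" for i in range(n)]
    alleles = genotypes.effect_allele or ["A"] * genotypes.n_variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chrSYN>\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for j, vid in enumerate(genotypes.variant_ids):
            alt = str(alleles[j]) if alleles[j] else "A"
            ref = "G" if alt == "A" else "A"
            vals = [
                "." if np.isnan(d) else f"{d:.6g}" for d in genotypes.dosage[:, j]
            ]
            fh.write(
                f"chrSYN\t{j + 1}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tDS\t" + "\t".join(vals) + "\n"
            )


def read_vcf_dosage(path) -> GenotypeMatrix:
    """Read a VCF's DS dosage field into a GenotypeMatrix (requires cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids: List[str] = []
    alleles: List[str] = []
    cols: List[np.ndarray] = []
    for variant in vcf:
        ids.append(variant.ID)
        alleles.append(variant.ALT[0] if variant.ALT else "A")
        ds = variant.format("DS")
        if ds is None:
            raise ValueError(f"VCF {path}: variant {variant.ID} lacks a DS field")
        col = np.asarray(ds, dtype=float).reshape(-1)
        col[col < 0] = np.nan  # cyvcf2 encodes missing as a negative sentinel
        cols.append(col)
    if not cols:
        raise ValueError(f"VCF {path} contains no variants")
    return GenotypeMatrix(np.column_stack(cols), ids, alleles)
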