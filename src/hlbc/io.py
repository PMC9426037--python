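"""Readers and writers for the pipeline's tabular artifacts.

Dialects follow MAF / cBioPortal conventions: TSV with a header row,
UTF-8, "." decimal. Variant tables are written with MAF-style column
names (Tumor_Sample_Barcode, Hugo_Symbol, ...) and mapped back to the
package's canonical columns on read. The expression matrix travels as a
CSV with genes as rows. Every writer/reader pair round-trips its table
exactly (column order, dtypes, values).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

MAF_COLUMN_MAP = {
    "sample_id": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "protein_change": "HGVSp_Short",
    "variant_type": "Variant_Type",
    "variant_classification": "Variant_Classification",
    "vaf": "t_VAF",
    "origin": "origin",
    "pathogenicity": "pathogenicity",
    "context96": "context96",
}
_MAF_REVERSE = {v: k for k, v in MAF_COLUMN_MAP.items()}

VARIANT_COLUMNS = list(MAF_COLUMN_MAP)
CLINICAL_COLUMNS = ["sample_id", "er_status", "pgr_pct", "grade", "ki67_pct",
                    "her2_class", "pam50", "cohort_tag"]
CN_COLUMNS = ["sample_id", "gene", "log10_fc"]
MSI_COLUMNS = ["sample_id", "locus", "call"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         na_values=[""])
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed TSV ({err})") from err
    _require_columns(df, required, path)
    return df


def _parse_float(df: pd.DataFrame, column: str, path) -> pd.Series:
    try:
        return df[column].astype(float)
    except ValueError:
        for lineno, value in enumerate(df[column], start=2):  # 1 header line
            try:
                float(value)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: line {lineno}: cannot parse {column}={value!r}"
                ) from None
        raise


def write_variants(variants: pd.DataFrame, path) -> None:
    out = variants[VARIANT_COLUMNS].rename(columns=MAF_COLUMN_MAP)
    out.to_csv(path, sep="\t", index=False)


def read_variants(path) -> pd.DataFrame:
    df = _read_tsv(path, list(MAF_COLUMN_MAP.values()))
    df = df.rename(columns=_MAF_REVERSE)[VARIANT_COLUMNS]
    df["vaf"] = _parse_float(df, "vaf", path)
    df["context96"] = df["context96"].where(df["context96"].notna(), None)
    return df


def write_clinical(samples: pd.DataFrame, path) -> None:
    samples[CLINICAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    df = _read_tsv(path, CLINICAL_COLUMNS)[CLINICAL_COLUMNS]
    for col in ("pgr_pct", "ki67_pct"):
        df[col] = _parse_float(df, col, path)
    return df


def write_cn_table(cn: pd.DataFrame, path) -> None:
    cn[CN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cn_table(path) -> pd.DataFrame:
    df = _read_tsv(path, CN_COLUMNS)[CN_COLUMNS]
    df["log10_fc"] = _parse_float(df, "log10_fc", path)
    return df


def write_msi_table(msi: pd.DataFrame, path) -> None:
    msi[MSI_COLUMNS].to_csv(path, sep="\t", index=False)


def read_msi_table(path) -> pd.DataFrame:
    return _read_tsv(path, MSI_COLUMNS)[MSI_COLUMNS]


def write_expression(expr: ExpressionMatrix, path) -> None:
    out = expr.values.copy()
    out.index.name = "gene"
    out.to_csv(path)


def read_expression(path, state: str = "raw") -> ExpressionMatrix:
    df = pd.read_csv(path, index_col=0)
    if df.index.name != "gene":
        raise ValueError(f"{path}: first column must be named 'gene'")
    values = df.astype(float)
    return ExpressionMatrix(values=values, state=state)


def write_pool(pool: pd.DataFrame, path) -> None:
    pool.to_csv(path, sep="\t", index=False)


def read_pool(path) -> pd.DataFrame:
    from .synth import POOL_CLINICAL_COLUMNS

    df = _read_tsv(path, POOL_CLINICAL_COLUMNS)
    for col in df.columns:
        if col not in POOL_CLINICAL_COLUMNS:
            df[col] = df[col].astype(int)
    return df


def write_gene_sets(gene_sets: dict[str, list[str]], path) -> None:
    """GMT format: name <tab> description <tab> genes..."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gene_sets(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT rows need "
                                 "name, description and >= 1 gene")
            sets[fields[0]] = fields[2:]
    return sets


def write_truth(truth: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_truth(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_loe_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_loe_table(path) -> pd.DataFrame:
    from .actionability import validate_loe_table

    df = _read_tsv(path, ["gene", "pattern", "pattern_type",
                          "oncokb_level", "escat_tier"])
    return validate_loe_table(df)


def write_cohort(cohort, outdir) -> dict[str, str]:
    """Write every table of a synthetic cohort; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": outdir / "clinical.tsv",
        "variants": outdir / "variants.maf.tsv",
        "cn": outdir / "cn_fold_change.tsv",
        "msi": outdir / "msi_calls.tsv",
        "expression": outdir / "expression.csv",
        "truth": outdir / "truth.json",
    }
    write_clinical(cohort.samples, paths["clinical"])
    write_variants(cohort.variants, paths["variants"])
    write_cn_table(cohort.cn_table, paths["cn"])
    write_msi_table(cohort.msi_table, paths["msi"])
    write_expression(cohort.expression, paths["expression"])
    write_truth(cohort.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
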