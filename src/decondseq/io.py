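"""TSV input/output.

All files are tab-separated, UTF-8, with '.' as the decimal separator.
Expression matrices carry gene_id in the first column and one column per
sample; floats are written with full precision (Python ``repr``) so that a
read -> write -> read round trip is exact.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .datatypes import (
    CATALOG_COLUMNS,
    SAMPLE_SHEET_COLUMNS,
    ExpressionMatrix,
    ValidationError,
    validate_catalog,
    validate_sample_sheet,
)


def read_expression(path, catalog: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a genes x samples TPM matrix from TSV.

    When a catalog is given, rows are reordered to catalog order and
    gene_ids absent from the catalog are dropped with a warning.

    Raises
    ------
    ValidationError
        On malformed rows, duplicate gene_ids or negative values.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", index_col="gene_id", dtype={"gene_id": str},
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"malformed expression TSV {path}: {exc}") from exc
    if df.isna().any().any():
        bad_rows = df.index[df.isna().any(axis=1)].tolist()
        raise ValidationError(f"malformed rows (missing fields) for genes: {bad_rows[:10]}")
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"duplicate gene rows: {dups}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric TPM value in {path}: {exc}") from exc
    if (df.to_numpy() < 0).any():
        bad = df.index[(df < 0).any(axis=1)].tolist()
        raise ValidationError(f"negative TPM values for genes: {bad[:10]}")
    if catalog is not None:
        validate_catalog(catalog)
        unknown = df.index.difference(catalog["gene_id"])
        if len(unknown) > 0:
            warnings.warn(
                f"{len(unknown)} gene_id(s) not in catalog were dropped: "
                f"{sorted(unknown)[:10]}",
                stacklevel=2,
            )
        order = [g for g in catalog["gene_id"] if g in df.index]
        df = df.loc[order]
    return ExpressionMatrix(values=df)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    # repr-formatting round-trips doubles exactly
    df.to_csv(path, sep="\t", float_format=None)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(
        path, sep="\t", dtype={c: str for c in SAMPLE_SHEET_COLUMNS if c not in ("age", "mapped_genic_reads")}
    )
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet[SAMPLE_SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_catalog(path) -> pd.DataFrame:
    catalog = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str})
    catalog["is_coding"] = catalog["is_coding"].astype(bool)
    return validate_catalog(catalog)


def write_catalog(catalog: pd.DataFrame, path) -> None:
    catalog[CATALOG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_lr_pairs(path) -> pd.DataFrame:
    """Ligand-receptor pair table TSV with columns (ligand, receptor)."""
    pairs = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ligand", "receptor"):
        if col not in pairs.columns:
            raise ValidationError(f"ligand-receptor table missing column {col!r}")
    if pairs.duplicated(["ligand", "receptor"]).any():
        raise ValidationError("duplicate (ligand, receptor) rows in pair table")
    return pairs


def read_receptor_expression(path) -> pd.Series:
    """Receptor -> TPM abundance profile of the target tissue (e.g. DRG)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if not {"gene", "tpm"} <= set(df.columns):
        raise ValidationError("receptor profile needs columns (gene, tpm)")
    if (df["tpm"] < 0).any():
        raise ValidationError("negative receptor abundance")
    return df.set_index("gene")["tpm"].astype(float)


def read_junction_counts(path) -> pd.DataFrame:
    """Long-format junction counts: (sample_id, junction_id, count)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "junction_id": str})
    need = {"sample_id", "junction_id", "count"}
    if not need <= set(df.columns):
        raise ValidationError(f"junction count table needs columns {sorted(need)}")
    counts = df["count"].to_numpy()
    if (counts < 0).any() or (counts != counts.astype(int)).any():
        raise ValidationError("junction counts must be nonnegative integers")
    df["count"] = df["count"].astype(int)
    return df


def read_junction_metadata(path) -> pd.DataFrame:
    """Junction annotations: (junction_id, exon_id, exon_length_bp, role)."""
    df = pd.read_csv(path, sep="\t", dtype={"junction_id": str, "exon_id": str, "role": str})
    need = {"junction_id", "exon_id", "exon_length_bp", "role"}
    if not need <= set(df.columns):
        raise ValidationError(f"junction metadata needs columns {sorted(need)}")
    if (df["exon_length_bp"] <= 0).any():
        raise ValidationError("exon lengths must be positive")
    bad_roles = set(df["role"]) - {"inclusion", "skipping"}
    if bad_roles:
        raise ValidationError(f"unknown junction roles: {sorted(bad_roles)}")
    return df
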