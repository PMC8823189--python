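"""Core containers and validation for the paired pre/post bed-rest study.

The analysis operates on four tabular objects, all carried as pandas
DataFrames with a thin layer of validation:

* a **sample sheet** — one row per biopsy (subject, pair, sex, intervention,
  timepoint, age, unambiguously mapped genic reads used as the library-size
  denominator for junction normalization);
* a **gene catalog** — gene_id, symbol and a protein-coding flag;
* an **expression matrix** — genes x samples of nonnegative TPM values,
  wrapped in :class:`ExpressionMatrix` to track whether coding-only
  renormalization has been applied;
* a **fold-change table** — genes x subjects of within-subject
  log2(post/baseline) ratios, wrapped in :class:`FoldChangeTable` together
  with the pseudocount used and an "unobserved" mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "subject_id",
    "pair_id",
    "sex",
    "intervention",
    "timepoint",
    "age",
    "mapped_genic_reads",
]

CATALOG_COLUMNS = ["gene_id", "symbol", "is_coding"]

TIMEPOINTS = ("baseline", "post")
INTERVENTIONS = ("control", "exercise")
SEXES = ("M", "F")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def validate_sample_sheet(sheet: pd.DataFrame, *, require_balanced_pairs: bool = False) -> pd.DataFrame:
    """Validate a sample sheet and return it unchanged.

    Checks column presence, categorical values, positive library sizes,
    uniqueness of sample ids, and that every subject has exactly one
    baseline and one post sample.  With ``require_balanced_pairs`` the
    one-control/one-exercise structure of two-subject pairs is also
    enforced (a pair of three subjects — the female trio — is accepted by
    the data model but never treated as a blinded pair).
    """
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet is missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id values: {dups}")
    for col, allowed in (("sex", SEXES), ("intervention", INTERVENTIONS), ("timepoint", TIMEPOINTS)):
        bad = set(sheet[col]) - set(allowed)
        if bad:
            raise ValidationError(f"invalid {col} values: {sorted(bad)} (allowed: {allowed})")
    if (sheet["mapped_genic_reads"] <= 0).any():
        bad = sheet.loc[sheet["mapped_genic_reads"] <= 0, "sample_id"].tolist()
        raise ValidationError(f"non-positive mapped_genic_reads for samples: {bad}")
    for subject, grp in sheet.groupby("subject_id"):
        tps = sorted(grp["timepoint"])
        if tps != ["baseline", "post"]:
            raise ValidationError(
                f"subject {subject!r} must have exactly one baseline and one post sample, got {tps}"
            )
    if require_balanced_pairs:
        for pair, grp in sheet.groupby("pair_id"):
            subjects = grp.drop_duplicates("subject_id")
            if len(subjects) == 2 and sorted(subjects["intervention"]) != ["control", "exercise"]:
                raise ValidationError(
                    f"pair {pair!r} must contain one control and one exercise subject"
                )
    return sheet


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene catalog (unique gene ids, boolean coding flag)."""
    missing = [c for c in CATALOG_COLUMNS if c not in catalog.columns]
    if missing:
        raise ValidationError(f"gene catalog is missing columns: {missing}")
    if catalog["gene_id"].duplicated().any():
        dups = catalog.loc[catalog["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"duplicate gene_id values in catalog: {dups}")
    return catalog


def blinded_pairs(sheet: pd.DataFrame) -> dict[str, list[str]]:
    """Pairs eligible for the blinded analysis: exactly two male subjects.

    The female trio (three subjects under one pair_id) is excluded, as are
    any pairs of non-male subjects; returns ``{pair_id: [subject_id, subject_id]}``
    with subjects in sorted order.
    """
    out: dict[str, list[str]] = {}
    for pair, grp in sheet.groupby("pair_id"):
        subjects = grp.drop_duplicates("subject_id")
        if len(subjects) == 2 and set(subjects["sex"]) == {"M"}:
            out[pair] = sorted(subjects["subject_id"])
    return out


def sample_of(sheet: pd.DataFrame, subject_id: str, timepoint: str) -> str:
    """Return the sample_id of ``subject_id`` at ``timepoint``."""
    hit = sheet[(sheet["subject_id"] == subject_id) & (sheet["timepoint"] == timepoint)]
    if len(hit) != 1:
        raise ValidationError(f"subject {subject_id!r} has no unique {timepoint} sample")
    return str(hit["sample_id"].iloc[0])


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of nonnegative TPM values.

    Parameters
    ----------
    values
        DataFrame indexed by gene_id with sample_id columns.
    renormalized
        True once coding-only renormalization (each sample summing to 1e6
        over coding genes) has been applied.
    """

    values: pd.DataFrame
    renormalized: bool = False

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression matrix contains negative TPM values")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene_id rows: {dups}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def check_renormalized(self, catalog: pd.DataFrame, rtol: float = 1e-6) -> bool:
        """Whether every sample's coding genes sum to one million within rtol."""
        coding = catalog.loc[catalog["is_coding"].astype(bool), "gene_id"]
        present = self.values.index.intersection(coding)
        sums = self.values.loc[present].sum(axis=0)
        return bool(np.allclose(sums, 1e6, rtol=rtol))


@dataclass
class FoldChangeTable:
    """Genes x subjects table of within-subject log2(post/baseline) ratios.

    ``epsilon`` is the pseudocount added to both numerator and denominator;
    ``unobserved`` marks (gene, subject) cells where baseline and post TPM
    were both below ``epsilon`` — such genes are excluded from the blinded
    per-subject lists to avoid 0/0 artifacts.
    """

    values: pd.DataFrame
    epsilon: float
    unobserved: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.unobserved is None:
            self.unobserved = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )

    @property
    def subjects(self) -> pd.Index:
        return self.values.columns

    def observed_values(self, subject_id: str) -> pd.Series:
        """Fold changes for one subject, restricted to observed genes."""
        mask = ~self.unobserved[subject_id]
        return self.values.loc[mask, subject_id]
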