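"""Coding-gene TPM renormalization and within-subject fold changes.

Upstream quantification reports TPM over the full gene annotation.  Because
non-coding RNA content varies between libraries, the analysis retains only
protein-coding genes and rescales each sample so the coding genes alone sum
to one million.  Fold changes are then computed per subject as
log2((post + eps) / (baseline + eps)) on the renormalized values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    ExpressionMatrix,
    FoldChangeTable,
    ValidationError,
    sample_of,
    validate_catalog,
    validate_sample_sheet,
)

DEFAULT_EPSILON = 0.01  # TPM pseudocount for ratios involving zeros


def renormalize_coding_tpm(matrix: ExpressionMatrix, catalog: pd.DataFrame) -> ExpressionMatrix:
    """Drop non-coding genes and rescale each sample to 1e6 total TPM.

    Scale-invariant and idempotent at the value level: a column already
    summing to 1e6 over coding genes is returned unchanged (up to floating
    point), and multiplying a column by any c > 0 beforehand yields
    identical output.

    Raises
    ------
    ValidationError
        If the matrix is already flagged renormalized, or if some sample
        has zero total coding expression (named in the message).
    """
    if matrix.renormalized:
        raise ValidationError("matrix is already renormalized")
    validate_catalog(catalog)
    coding = catalog.loc[catalog["is_coding"].astype(bool), "gene_id"]
    present = [g for g in coding if g in matrix.values.index]
    if not present:
        raise ValidationError("no coding genes present in the matrix")
    sub = matrix.values.loc[present]
    totals = sub.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValidationError(f"samples with zero coding expression: {zero}")
    scaled = sub * (1e6 / totals)
    return ExpressionMatrix(values=scaled, renormalized=True)


def compute_log2_fold_changes(
    matrix: ExpressionMatrix,
    sheet: pd.DataFrame,
    epsilon: float = DEFAULT_EPSILON,
) -> FoldChangeTable:
    """Per-gene, per-subject log2((post + eps) / (baseline + eps)).

    Requires every subject in the sheet to have both timepoints.  Genes
    whose baseline and post TPM are both below ``epsilon`` in a subject are
    marked unobserved for that subject (excluded from blinded lists
    downstream); their numeric value is still returned and is finite.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    validate_sample_sheet(sheet)
    subjects = sorted(sheet["subject_id"].unique())
    cols = {}
    unobs = {}
    for subject in subjects:
        base = matrix.values[sample_of(sheet, subject, "baseline")]
        post = matrix.values[sample_of(sheet, subject, "post")]
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.log2((post + epsilon) / (base + epsilon))
        cols[subject] = fc
        unobs[subject] = (base < epsilon) & (post < epsilon)
    values = pd.DataFrame(cols, index=matrix.values.index)
    unobserved = pd.DataFrame(unobs, index=matrix.values.index)
    if epsilon == 0:
        # 0/0 and log2(0) produce non-finite entries; mark them unobserved
        unobserved |= ~np.isfinite(values)
    return FoldChangeTable(values=values, epsilon=epsilon, unobserved=unobserved)


class CodingTPMNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer wrapping :func:`renormalize_coding_tpm`.

    Parameters
    ----------
    catalog
        Gene catalog with (gene_id, symbol, is_coding).

    Attributes
    ----------
    coding_genes_ : list of str
        Coding gene_ids retained at fit time.
    """

    def __init__(self, catalog: pd.DataFrame | None = None):
        self.catalog = catalog

    def fit(self, X: ExpressionMatrix, y=None):
        if self.catalog is None:
            raise ValueError("CodingTPMNormalizer requires a gene catalog")
        validate_catalog(self.catalog)
        coding = self.catalog.loc[self.catalog["is_coding"].astype(bool), "gene_id"]
        self.coding_genes_ = [g for g in coding if g in X.values.index]
        return self

    def transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        return renormalize_coding_tpm(X, self.catalog)
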