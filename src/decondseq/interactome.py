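"""Muscle-to-sensory-neuron ligand-receptor interactome.

Upregulated, significant DEGs from a muscle group are intersected with a
ligand-receptor pair database; a ligand is retained only if at least one
of its known receptors is expressed — abundance >= tau TPM — in a target
tissue profile (human dorsal root ganglion neurons).  Each output row
lists the ligand, its adjusted p-value, and its expressed receptors in
descending target-tissue abundance.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import ValidationError

DEFAULT_TAU = 1.0  # TPM threshold for "expressed" in the target tissue


def build_interactome(
    deg_table: pd.DataFrame,
    pairs: pd.DataFrame,
    receptor_expression: pd.Series,
    tau: float = DEFAULT_TAU,
    catalog: pd.DataFrame | None = None,
    alias_map: dict[str, str] | None = None,
    direction: str = "up",
) -> pd.DataFrame:
    """Intersect directional DEGs with the ligand-receptor database.

    Parameters
    ----------
    deg_table
        Per-gene DE results (index gene_id; columns log2fc, adj_p,
        significant).
    pairs
        (ligand, receptor) rows, gene symbols.
    receptor_expression
        receptor symbol -> target-tissue TPM.
    tau
        Abundance threshold (inclusive) for an expressed receptor.
    catalog
        Optional gene catalog to map gene_id -> symbol; without it the DE
        index is assumed to be symbols already.
    alias_map
        Optional symbol aliases applied to the DEG symbols before matching.
    direction
        "up" (the default, as in the study) or "down".

    Returns
    -------
    DataFrame with columns (ligand, adj_p, receptors) sorted by ligand
    symbol; ``receptors`` is a comma-joined list in descending abundance,
    ties broken lexicographically.
    """
    if pairs.empty:
        raise ValidationError("empty ligand-receptor pair database")
    if pairs.duplicated(["ligand", "receptor"]).any():
        raise ValidationError("duplicate (ligand, receptor) rows")
    if tau < 0 or (receptor_expression < 0).any():
        raise ValidationError("receptor abundances and tau must be nonnegative")

    sig = deg_table[deg_table["significant"]]
    sig = sig[sig["log2fc"] > 0] if direction == "up" else sig[sig["log2fc"] < 0]

    to_symbol = (
        catalog.set_index("gene_id")["symbol"].to_dict() if catalog is not None else {}
    )
    alias = alias_map or {}
    symbol_p: dict[str, float] = {}
    for gid in sig.index:
        symbol = alias.get(to_symbol.get(gid, gid), to_symbol.get(gid, gid))
        symbol_p[symbol] = float(sig.loc[gid, "adj_p"])

    rows = []
    for ligand, grp in pairs.groupby("ligand"):
        if ligand not in symbol_p:
            continue
        receptors = [
            r
            for r in grp["receptor"]
            if r in receptor_expression.index and receptor_expression[r] >= tau
        ]
        if not receptors:
            continue
        receptors.sort(key=lambda r: (-receptor_expression[r], r))
        rows.append(
            {"ligand": ligand, "adj_p": symbol_p[ligand], "receptors": ", ".join(receptors)}
        )
    out = pd.DataFrame(rows, columns=["ligand", "adj_p", "receptors"])
    return out.sort_values("ligand", ignore_index=True)


class InteractomeBuilder(BaseEstimator):
    """Estimator wrapper: ``fit`` stores the database, ``transform`` maps a
    DEG table to its interactome rows."""

    def __init__(self, tau: float = DEFAULT_TAU, direction: str = "up",
                 alias_map: dict[str, str] | None = None):
        self.tau = tau
        self.direction = direction
        self.alias_map = alias_map

    def fit(self, pairs: pd.DataFrame, receptor_expression: pd.Series):
        if pairs.empty:
            raise ValidationError("empty ligand-receptor pair database")
        self.pairs_ = pairs
        self.receptor_expression_ = receptor_expression
        return self

    def transform(self, deg_table: pd.DataFrame, catalog: pd.DataFrame | None = None) -> pd.DataFrame:
        return build_interactome(
            deg_table,
            self.pairs_,
            self.receptor_expression_,
            tau=self.tau,
            catalog=catalog,
            alias_map=self.alias_map,
            direction=self.direction,
        )
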