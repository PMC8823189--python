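"""Junction-level splice-variant quantification.

Bridge reads spanning the exon-exon junctions of a targeted exon
inclusion/skipping event are normalized per sample to Reads per Million
mapped reads (RPM; the denominator is the library's unambiguously mapped
genic reads) and per kilobase of exon length (RPKM).  Group-level
abundances pool raw counts over the group's samples and divide by the
summed library sizes — not the mean of per-sample RPMs — so deeper
libraries carry proportionally more weight.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ValidationError

DEFAULT_RPM_THRESHOLD = 0.5


def rpm(count, mapped_reads):
    """Reads per million mapped reads: count / (mapped_reads / 1e6)."""
    mapped = np.asarray(mapped_reads, dtype=float)
    if (mapped <= 0).any():
        raise ValidationError("mapped_reads must be positive")
    return np.asarray(count, dtype=float) / (mapped / 1e6)


def rpkm(count, exon_length_bp, mapped_reads):
    """RPM additionally normalized per kilobase of exon length."""
    length = np.asarray(exon_length_bp, dtype=float)
    if (length <= 0).any():
        raise ValidationError("exon_length_bp must be positive")
    return rpm(count, mapped_reads) / (length / 1000.0)


def per_sample_abundance(
    counts: pd.DataFrame, metadata: pd.DataFrame, sheet: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample RPM and RPKM for every (sample, junction) row."""
    unknown = set(counts["sample_id"]) - set(sheet["sample_id"])
    if unknown:
        raise ValidationError(f"junction counts reference unknown samples: {sorted(unknown)}")
    libs = sheet.set_index("sample_id")["mapped_genic_reads"]
    lengths = metadata.set_index("junction_id")["exon_length_bp"]
    out = counts.copy()
    out["mapped_genic_reads"] = out["sample_id"].map(libs).astype(float)
    out["exon_length_bp"] = out["junction_id"].map(lengths).astype(float)
    out["rpm"] = rpm(out["count"], out["mapped_genic_reads"])
    out["rpkm"] = rpkm(out["count"], out["exon_length_bp"], out["mapped_genic_reads"])
    return out


def pooled_group_abundance(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    sheet: pd.DataFrame,
    grouping: str = "intervention",
) -> pd.DataFrame:
    """Pooled per-group junction abundance.

    For every (group, junction): summed counts over the group's samples,
    normalized by the summed library sizes (RPM) and the exon length
    (RPKM).  Every sample in the counts table must carry a group label in
    the sheet.
    """
    per_sample = per_sample_abundance(counts, metadata, sheet)
    groups = sheet.set_index("sample_id")[grouping]
    per_sample["group"] = per_sample["sample_id"].map(groups)
    if per_sample["group"].isna().any():
        bad = per_sample.loc[per_sample["group"].isna(), "sample_id"].tolist()
        raise ValidationError(f"samples without a group label: {bad}")
    rows = []
    for (group, jx), grp in per_sample.groupby(["group", "junction_id"]):
        total_lib = grp["mapped_genic_reads"].sum()
        if total_lib <= 0:
            raise ValidationError(f"group {group!r} has zero total library size")
        total = grp["count"].sum()
        length = float(grp["exon_length_bp"].iloc[0])
        rows.append(
            {
                "group": group,
                "junction_id": jx,
                "n_samples": len(grp),
                "total_count": int(total),
                "pooled_rpm": float(rpm(total, total_lib)),
                "pooled_rpkm": float(rpkm(total, length, total_lib)),
            }
        )
    return pd.DataFrame(rows).sort_values(["group", "junction_id"], ignore_index=True)


def call_expressed(abundances: pd.Series, threshold: float = DEFAULT_RPM_THRESHOLD):
    """Strictly-above-threshold detection calls.

    Returns (per-sample boolean flags, number of samples above threshold).
    The comparison is strict: a value exactly at the threshold is *not*
    called.
    """
    if threshold < 0:
        raise ValidationError("threshold must be nonnegative")
    flags = abundances > threshold
    return flags, int(flags.sum())
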