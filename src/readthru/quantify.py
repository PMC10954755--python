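"""Region-count quantification of readthrough efficiency.

Readthrough efficiency (RE) of a transcript is the log2 ratio of
extension-region RPKM to CDS RPKM.  Transcripts with too little coverage
(CDS RPKM < 5) or undetectable readthrough (extension RPKM < 0.5) are
discarded; of the remaining transcripts, the top and bottom 15% by RE are
labelled "high" and "low" for the classification model.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

RPKM_CDS_MIN = 5.0
RPKM_EXT_MIN = 0.5
EXTREME_FRACTION = 0.15

COUNTS_COLUMNS = [
    "transcript_id", "cds_count", "ext_count", "cds_len", "ext_len", "library_size",
]


def rpkm(count: float, region_len: int, library_size: int) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if region_len <= 0:
        raise ValueError("region length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / (region_len / 1_000) / (library_size / 1_000_000)


def compute_readthrough(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript RPKMs and log2 RE from a region-count table.

    Expects columns ``transcript_id, cds_count, ext_count, cds_len,
    ext_len, library_size``.  Records with an empty extension region, or a
    zero RPKM on either side, get ``log2_re = NaN`` and are flagged
    non-quantifiable.
    """
    missing = set(COUNTS_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    out = counts.copy()
    lib = out["library_size"].to_numpy(dtype=np.float64)
    if (lib <= 0).any():
        raise ValueError("library size must be positive")
    cds_len = out["cds_len"].to_numpy(dtype=np.float64)
    ext_len = out["ext_len"].to_numpy(dtype=np.float64)
    if (cds_len <= 0).any():
        raise ValueError("CDS length must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rpkm_cds"] = out["cds_count"] / (cds_len / 1e3) / (lib / 1e6)
        rpkm_ext = np.where(
            ext_len > 0,
            out["ext_count"] / np.where(ext_len > 0, ext_len, 1) * 1e3 / (lib / 1e6),
        0.0)
        out["rpkm_ext"] = rpkm_ext
        ratio = out["rpkm_ext"] / out["rpkm_cds"]
        out["log2_re"] = np.where(
            (out["rpkm_ext"] > 0) & (out["rpkm_cds"] > 0), np.log2(ratio), np.nan
        )
    out["quantifiable"] = (ext_len > 0) & out["log2_re"].notna()
    return out


def filter_detectable(
    table: pd.DataFrame,
    rpkm_cds_min: float = RPKM_CDS_MIN,
    rpkm_ext_min: float = RPKM_EXT_MIN,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep records with CDS RPKM >= 5 and extension RPKM >= 0.5.

    Discarding uses the union of the two failure conditions (a record
    failing either is dropped); the returned counter reports how many
    records each reason removed, with records failing only one condition
    counted separately for transparency.
    """
    low_cds = table["rpkm_cds"] < rpkm_cds_min
    low_ext = table["rpkm_ext"] < rpkm_ext_min
    kept = table.loc[~(low_cds | low_ext)].copy()
    kept["detectable"] = True
    reasons = {
        "low_cds_rpkm_only": int((low_cds & ~low_ext).sum()),
        "low_ext_rpkm_only": int((low_ext & ~low_cds).sum()),
        "both": int((low_cds & low_ext).sum()),
    }
    return kept, reasons


def label_extremes(
    table: pd.DataFrame, fraction: float = EXTREME_FRACTION
) -> pd.DataFrame:
    """Label the top/bottom ``fraction`` of detectable records by log2 RE.

    Exactly floor(fraction * n) records receive each label; ties at the
    boundary break deterministically on (log2_re, transcript_id), so the
    labelling is invariant to input row order.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    out = table.copy()
    n = len(out)
    k = math.floor(fraction * n)
    order = out.sort_values(
        ["log2_re", "transcript_id"], ascending=[True, True]
    ).index
    out["extreme_label"] = "none"
    out.loc[order[:k], "extreme_label"] = "low"
    if k > 0:
        out.loc[order[-k:], "extreme_label"] = "high"
    return out


def read_counts_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_log2_re_table(path) -> pd.DataFrame:
    """Pre-computed log2 readthrough efficiencies: transcript_id, log2_re."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"transcript_id", "log2_re"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns transcript_id, log2_re")
    return df
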