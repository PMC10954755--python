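"""Comparative statistics on readthrough efficiency.

* Group-vs-sample median differences with two-tailed Wilcoxon rank-sum
  tests and Benjamini-Hochberg correction (stop codon, flanking
  nucleotides, stop+nt+4 quadruplets, P-site codons, negative-control
  letters).
* Chi-squared test of association between stop-codon and nt+4 identities
  with adjusted standardized residuals for per-cell interpretation.
* Spearman correlations (readthrough efficiency vs 3'-UTR length or MFE),
  optionally restricted to 100 < length < 5000 nt.
* Context frequency tables (stop, nt+4, quadruplet usage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

MIN_GROUP_N = 5
EXACT_WILCOXON_MAX_N = 50


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(x, y) -> float:
    """Two-tailed Wilcoxon rank-sum p-value.

    Exact distribution when both groups are small (<= 50) and tie-free;
    otherwise the normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    small = max(len(x), len(y)) <= EXACT_WILCOXON_MAX_N
    method = "exact" if (no_ties and small) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def group_median_analysis(
    log2_re,
    groups,
    grouping_name: str,
    min_n: int = MIN_GROUP_N,
    mode: str = "sample",
) -> pd.DataFrame:
    """Median shift of each group against the sample median, with Wilcoxon/BH.

    ``mode="sample"`` compares each group against the full sample
    (including the group itself, matching the "sample median" convention);
    ``mode="complement"`` compares against the remaining records.  Levels
    with fewer than ``min_n`` members are reported but flagged.
    """
    values = np.asarray(log2_re, dtype=float)
    groups = np.asarray(groups)
    if len(values) == 0:
        raise ValueError("empty input")
    if len(values) != len(groups):
        raise ValueError("length mismatch")
    if mode not in ("sample", "complement"):
        raise ValueError(f"unknown mode {mode!r}")
    sample_median = float(np.median(values))
    rows = []
    for level in sorted(pd.unique(groups)):
        in_group = groups == level
        gv = values[in_group]
        ref = values if mode == "sample" else values[~in_group]
        if len(gv) and len(ref):
            p = wilcoxon_rank_sum(gv, ref)
        else:
            p = np.nan
        rows.append({
            "grouping": grouping_name,
            "level": level,
            "n": int(in_group.sum()),
            "delta_median": float(np.median(gv) - sample_median),
            "p": p,
            "small_group": bool(in_group.sum() < min_n),
        })
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass
class Chi2Result:
    observed: pd.DataFrame       # stop (rows) x nt+4 (columns)
    expected: pd.DataFrame
    std_residuals: pd.DataFrame  # adjusted standardized residuals
    raw_residuals: pd.DataFrame  # Pearson residuals (O-E)/sqrt(E)
    cell_p: pd.DataFrame         # two-tailed per-cell p from N(0,1)
    chi2: float
    dof: int
    p: float


def chi2_stop_nt4(
    stop, nt4, expected: str = "independence",
    stop_levels=None, nt4_levels=None,
) -> Chi2Result:
    """Association between stop-codon and nt+4 identities.

    ``expected="independence"`` uses the product of margins (the test of
    independence); ``expected="uniform"`` spreads each stop codon's total
    equally over the observed nt+4 levels (the equal-frequency reading).
    Residuals are adjusted standardized residuals,
    (O-E)/sqrt(E(1-row_prop)(1-col_prop)), referred to N(0,1) per cell.
    """
    obs = pd.crosstab(pd.Series(stop, name="stop"), pd.Series(nt4, name="nt4"))
    obs = obs.sort_index(axis=0).sort_index(axis=1)
    if stop_levels is not None:
        obs = obs.reindex(index=list(stop_levels), fill_value=0)
    if nt4_levels is not None:
        obs = obs.reindex(columns=list(nt4_levels), fill_value=0)
    rows_zero = obs.sum(axis=1) == 0
    cols_zero = obs.sum(axis=0) == 0
    if rows_zero.any() or cols_zero.any():
        offending = list(obs.index[rows_zero]) + list(obs.columns[cols_zero])
        raise ValueError(f"zero margin for level(s) {offending}")
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least two levels of each factor")
    O = obs.to_numpy(dtype=float)
    total = O.sum()
    row = O.sum(axis=1, keepdims=True)
    col = O.sum(axis=0, keepdims=True)
    if expected == "independence":
        E = row @ col / total
    elif expected == "uniform":
        E = np.repeat(row / O.shape[1], O.shape[1], axis=1)
    else:
        raise ValueError(f"unknown expected model {expected!r}")
    chi2 = float(((O - E) ** 2 / E).sum())
    dof = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, dof))
    raw = (O - E) / np.sqrt(E)
    rprop = row / total
    cprop = col / total
    adj = (O - E) / np.sqrt(E * (1 - rprop) * (1 - cprop))
    cell_p = 2 * sps.norm.sf(np.abs(adj))
    wrap = lambda a: pd.DataFrame(a, index=obs.index, columns=obs.columns)
    return Chi2Result(obs, wrap(E), wrap(adj), wrap(raw), wrap(cell_p),
                      chi2, dof, p)


def correlate(
    x, y, x_range: tuple[float, float] | None = None
) -> tuple[float, float, int]:
    """Spearman correlation (midrank ties) of y against x.

    ``x_range=(lo, hi)`` restricts to lo < x < hi (strict), as in the
    100 < 3'-UTR length < 5000 nt sensitivity analysis.  Returns
    (rho, p, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if x_range is not None:
        lo, hi = x_range
        keep &= (x > lo) & (x < hi)
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise ValueError(f"need >= 4 finite pairs, got {len(x)}")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p), int(len(x))


def context_frequency_table(records) -> pd.DataFrame:
    """Counts and proportions of stop codons, nt+4, and quadruplets.

    One tidy table with columns family, level, count, proportion;
    proportions sum to 1 within each family.
    """
    if not records:
        raise ValueError("empty input")
    stops, nt4s, quads = [], [], []
    for r in records:
        stop = r.stop_codon
        after = r.sequence[r.stop_offset + 3:r.stop_offset + 4]
        stops.append(stop)
        if after:
            nt4s.append(after)
            quads.append(stop + after)
    rows = []
    for family, items in (("stop", stops), ("nt4", nt4s), ("quadruplet", quads)):
        counts = pd.Series(items).value_counts().sort_index()
        total = counts.sum()
        for level, count in counts.items():
            rows.append({
                "family": family, "level": level,
                "count": int(count), "proportion": count / total,
            })
    return pd.DataFrame(rows)
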