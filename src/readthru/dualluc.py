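"""Dual-luciferase readthrough assay processing.

Readthrough level of one well is firefly activity normalized to Renilla
activity, in percent.  Within each quadruplicate set, wells are excluded
while the replicate coefficient of variation (SD/AVE) exceeds 25%,
removing the well farthest from the current mean at each step and never
going below two wells.  The response to G418 of an allele is the log2
fold-change of mean readthrough (treated over untreated) per independent
experiment, averaged across experiments; alleles are then compared
between stop-codon groups with pairwise two-tailed Student's t-tests
under Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

OUTLIER_CV_PERCENT = 25.0
MIN_WELLS = 2

PLATE_COLUMNS = ["allele", "experiment", "condition", "well", "firefly", "renilla"]
CONDITIONS = ("untreated", "G418")


@dataclass
class LucExperiment:
    """Replicate wells of one allele x experiment x condition."""

    allele: str
    experiment_id: str
    condition: str
    wells: list[tuple[float, float]]  # (firefly, renilla)


@dataclass
class AssayResult:
    allele: str
    mean_readthrough: dict  # condition -> mean percent over experiments
    response: float  # mean log2 fold-change (G418/untreated) over experiments
    n_experiments: int
    excluded_wells: list = field(default_factory=list)
    flags: list = field(default_factory=list)


def readthrough_level(firefly: float, renilla: float) -> float:
    """firefly / Renilla x 100 (percent)."""
    if renilla <= 0:
        raise ValueError("Renilla signal must be positive")
    if firefly < 0:
        raise ValueError("firefly signal must be non-negative")
    return firefly / renilla * 100.0


def _cv_percent(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        return np.nan
    return float(values.std(ddof=1) / mean * 100.0)


def exclude_outlier_wells(
    values,
    threshold: float = OUTLIER_CV_PERCENT,
    iterative: bool = True,
) -> tuple[np.ndarray, list[dict], list[str]]:
    """Drop replicate wells while SD/AVE% exceeds the threshold.

    Removal is farthest-from-mean first and recomputes after every
    exclusion (``iterative=False`` stops after one pass), never dropping
    below two wells.  Input order does not affect the result.  Returns
    (retained values, exclusion log, flags).
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 3:
        raise ValueError("need at least 3 wells to consider exclusions")
    retained = np.sort(vals)[::-1]  # deterministic processing order
    exclusions: list[dict] = []
    flags: list[str] = []
    while True:
        cv = _cv_percent(retained)
        if np.isnan(cv):
            flags.append("SD/AVE undefined (zero mean)")
            break
        if cv <= threshold:
            break
        if len(retained) <= MIN_WELLS:
            flags.append("unresolved dispersion at minimum well count")
            break
        far = np.argmax(np.abs(retained - retained.mean()))
        removed = retained[far]
        after = np.delete(retained, far)
        exclusions.append({
            "value": float(removed),
            "sd_ave_before": cv,
            "sd_ave_after": _cv_percent(after),
        })
        retained = after
        if not iterative:
            if _cv_percent(retained) > threshold and len(retained) > MIN_WELLS:
                flags.append("dispersion still above threshold after single pass")
            break
    return retained, exclusions, flags


def g418_response(experiments: list[LucExperiment]) -> AssayResult:
    """Per-allele G418 response from paired treated/untreated experiments."""
    alleles = {e.allele for e in experiments}
    if len(alleles) != 1:
        raise ValueError(f"experiments span multiple alleles: {sorted(alleles)}")
    allele = alleles.pop()
    by_exp: dict[str, dict[str, LucExperiment]] = {}
    for e in experiments:
        if e.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {e.condition!r}")
        by_exp.setdefault(e.experiment_id, {})[e.condition] = e

    responses, excluded, flags = [], [], []
    cond_means: dict[str, list[float]] = {c: [] for c in CONDITIONS}
    for exp_id in sorted(by_exp):
        pair = by_exp[exp_id]
        if set(pair) != set(CONDITIONS):
            flags.append(f"{exp_id}: missing condition, skipped")
            continue
        means = {}
        for cond, exp in pair.items():
            levels = np.array([readthrough_level(f, r) for f, r in exp.wells])
            if len(levels) >= 3:
                kept, excl, fl = exclude_outlier_wells(levels)
            else:
                kept, excl, fl = levels, [], []
            excluded.extend(
                {"experiment": exp_id, "condition": cond, **e} for e in excl
            )
            flags.extend(f"{exp_id}/{cond}: {f}" for f in fl)
            means[cond] = float(kept.mean())
        if means["untreated"] == 0:
            flags.append(f"{exp_id}: untreated mean is zero, skipped")
            continue
        for cond in CONDITIONS:
            cond_means[cond].append(means[cond])
        responses.append(np.log2(means["G418"] / means["untreated"]))
    if not responses:
        raise ValueError(f"{allele}: no usable experiment pairs")
    return AssayResult(
        allele=allele,
        mean_readthrough={c: float(np.mean(v)) for c, v in cond_means.items()},
        response=float(np.mean(responses)),
        n_experiments=len(responses),
        excluded_wells=excluded,
        flags=flags,
    )


def compare_response_by_stop(
    results: list[AssayResult], stops: dict[str, str]
) -> pd.DataFrame:
    """Pairwise t-tests of G418 response between stop-codon groups.

    The three pairs UGA-UAG, UGA-UAA, UAG-UAA are tested with two-sample
    two-tailed Student's t-tests; BH correction runs over the tested
    pairs.  Pairs with a group of fewer than two alleles are skipped with
    a flag.
    """
    by_stop: dict[str, list[float]] = {}
    for r in results:
        by_stop.setdefault(stops[r.allele], []).append(r.response)
    rows = []
    for a, b in (("UGA", "UAG"), ("UGA", "UAA"), ("UAG", "UAA")):
        ga, gb = by_stop.get(a, []), by_stop.get(b, [])
        if len(ga) < 2 or len(gb) < 2:
            rows.append({"pair": f"{a}-{b}", "mean_a": np.nan, "mean_b": np.nan,
                         "p": np.nan, "skipped": True})
            continue
        t = sps.ttest_ind(ga, gb, equal_var=True)
        pvalue = float(t.pvalue)
        if np.isnan(pvalue) and np.mean(ga) == np.mean(gb):
            pvalue = 1.0  # zero variance, zero difference: no evidence
        rows.append({
            "pair": f"{a}-{b}",
            "mean_a": float(np.mean(ga)),
            "mean_b": float(np.mean(gb)),
            "p": pvalue,
            "skipped": False,
        })
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out


def read_plate_csv(path) -> list[LucExperiment]:
    """Plate data CSV: allele,experiment,condition,well,firefly,renilla."""
    df = pd.read_csv(path, comment="#")
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    experiments = []
    for (allele, exp, cond), grp in df.groupby(
        ["allele", "experiment", "condition"], sort=True
    ):
        wells = list(zip(grp["firefly"].astype(float), grp["renilla"].astype(float)))
        experiments.append(LucExperiment(str(allele), str(exp), str(cond), wells))
    return experiments
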