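#!/usr/bin/env python
"""Comparative statistics of stop-codon context vs readthrough efficiency.

Group-median shifts (stop codon, nt+4, quadruplets, P-site codons, and
the random-letter negative control) with Wilcoxon/BH, the chi-squared
association between stop and nt+4 identities, and the Spearman
correlation of readthrough efficiency with 3'-UTR length (full and
100-5000 nt restricted).
"""

import argparse
from pathlib import Path

import pandas as pd

from readthru.io import read_table, write_table
from readthru.stats import chi2_stop_nt4, correlate, group_median_analysis


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    features = read_table(args.out / "features.tsv")
    readthrough = read_table(args.out / "readthrough.tsv")
    merged = features.merge(readthrough[["transcript_id", "log2_re"]],
                            on="transcript_id")
    y = merged["log2_re"].to_numpy()

    groupings = {
        "stop": merged["stop_codon"],
        "nt_p4": merged["nt_p4"],
        "quadruplet": merged["stop_codon"] + merged["nt_p4"],
        "psite_codon": merged["psite_codon"],
        "nc_letter": merged["nc_letter"],
    }
    tables = [group_median_analysis(y, g.to_numpy(), name)
              for name, g in groupings.items()]
    gm = pd.concat(tables, ignore_index=True)
    write_table(gm, args.out / "group_medians.tsv")

    stop = tables[0].set_index("level")
    print("stop-codon median shifts (delta vs sample median, q-value):")
    for level in ("UGA", "UAG", "UAA"):
        print(f"  {level}: {stop.loc[level, 'delta_median']:+.3f} "
              f"(q={stop.loc[level, 'q']:.2e}, n={stop.loc[level, 'n']})")
    nc = tables[-1]
    print(f"random-letter groups with q<0.05: {(nc['q'] < 0.05).sum()} of {len(nc)}")

    chi2 = chi2_stop_nt4(merged["stop_codon"], merged["nt_p4"])
    write_table(chi2.std_residuals.reset_index(), args.out / "chi2_residuals.tsv",
                {"chi2": round(chi2.chi2, 3), "p": chi2.p})
    print(f"stop x nt+4 chi2 = {chi2.chi2:.1f} (p={chi2.p:.2e})")

    rows = []
    for label, rng in (("all", None), ("100-5000nt", (100.0, 5000.0))):
        rho, p, n = correlate(merged["utr3_len"], y, x_range=rng)
        rows.append({"analysis": label, "rho": rho, "p": p, "n": n})
        print(f"log2 RE vs 3'-UTR length ({label}): rho={rho:.3f}, n={n}")
    write_table(pd.DataFrame(rows), args.out / "length_correlations.tsv")


if __name__ == "__main__":
    main()
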