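#!/usr/bin/env python
"""Train random-forest models of readthrough efficiency.

Extracts the 75+2 stop-codon-context features, trains the regression
(log2 RE) and classification (high vs low) forests with 100 trees and
5-fold CV over mtry, and writes OOB permutation importance tables.  The
negative-control features set the importance baseline; the planted stop
codon, nt+4, and 3'-UTR length should clear it.
"""

import argparse
from pathlib import Path

from readthru.catalog import read_catalog
from readthru.features import attach_negative_controls, default_schema, extract_feature_table
from readthru.forest import (
    ModelSpec,
    permutation_importance,
    train_classifier,
    train_regressor,
)
from readthru.io import read_table, write_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    records, _ = read_catalog(args.data / "catalog.fasta", args.data / "regions.tsv")
    schema = default_schema()
    features, _ = extract_feature_table(records, schema)
    features = attach_negative_controls(features, seed=args.seed + 1)
    write_table(features, args.out / "features.tsv", {"schema": schema.name})

    readthrough = read_table(args.out / "readthrough.tsv")
    merged = features.merge(
        readthrough[["transcript_id", "log2_re", "extreme_label"]],
        on="transcript_id")

    reg = train_regressor(merged, merged["log2_re"].to_numpy(),
                          ModelSpec(task="regression", seed=args.seed), schema)
    reg.save(args.out / "regression_model.pkl")
    imp = permutation_importance(reg, merged, merged["log2_re"].to_numpy())
    write_table(imp.sort_values("rank"), args.out / "importance_incmse.tsv",
                {"metric": "%IncMSE", "mtry": reg.mtry})
    print(f"regression: mtry={reg.mtry}, CV NRMSE={reg.cv_metric:.4f}")
    top = imp.sort_values("rank").head(5)
    print("top %IncMSE features:",
          ", ".join(f"{r.feature} ({r.importance:.1f})" for r in top.itertuples()))

    extremes = merged[merged["extreme_label"].isin(["high", "low"])]
    clf = train_classifier(extremes, extremes["extreme_label"].to_numpy(),
                           ModelSpec(task="classification", seed=args.seed),
                           schema)
    clf.save(args.out / "classification_model.pkl")
    cimp = permutation_importance(clf, extremes,
                                  extremes["extreme_label"].to_numpy())
    write_table(cimp.sort_values("rank"), args.out / "importance_mda.tsv",
                {"metric": "MDA", "mtry": clf.mtry})
    print(f"classification: mtry={clf.mtry}, CV AUROC={clf.cv_metric:.4f}")
    nc = imp.set_index("feature").loc[["nc_number", "nc_letter"], "rank"]
    print(f"negative-control ranks (%IncMSE): {nc.to_dict()} of {len(imp)}")


if __name__ == "__main__":
    main()
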