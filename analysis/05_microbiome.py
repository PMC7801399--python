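#!/usr/bin/env python
"""Associate gut-microbiome composition with anxiety group.

Family-level and OTU-level Mann-Whitney screens with BH correction
(FDR < 0.1 and < 0.05), per-SD logistic odds ratios for the flagged
families, and a 1000-tree random forest (100 stratified 90/10 iterations)
predicting HA/LA from the flagged families with pooled ROC/AUC.
"""

from pathlib import Path

import pandas as pd

from anxmediate import io, microassoc, pipeline

ROOT = Path(__file__).resolve().parents[1]
CFG = Path(__file__).resolve().parent / "config.yaml"


def main() -> None:
    cfg = pipeline.load_config(CFG)
    table, taxonomy = io.read_abundance(ROOT / "results" / "sim" / "abundance.tsv")
    labels = pd.read_csv(ROOT / "results" / "labels.csv", index_col="mouse_id")["anxiety"]

    fam = microassoc.differential_abundance(
        table, labels, level="family", taxonomy=taxonomy, fdr=cfg.thresholds.family_fdr
    )
    fam.to_csv(ROOT / "results" / "family_tests.csv", index=False)
    flagged = fam.loc[fam["significant"]].sort_values("q")
    print(f"families different between HA and LA (FDR<{cfg.thresholds.family_fdr}): "
          f"{len(flagged)}/{len(fam)}")
    for r in flagged.itertuples(index=False):
        arrow = "higher" if r.direction > 0 else "lower"
        print(f"  {r.taxon}: q={r.q:.2e}, {arrow} in HA")

    otu = microassoc.differential_abundance(table, labels, level="otu", fdr=cfg.thresholds.otu_fdr)
    otu.to_csv(ROOT / "results" / "otu_tests.csv", index=False)
    print(f"OTUs different at FDR<{cfg.thresholds.otu_fdr}: {int(otu['significant'].sum())}/{len(otu)}")

    taxa = flagged["taxon"].tolist()
    odds = microassoc.taxon_logistic(table, labels, taxa, taxonomy=taxonomy)
    odds.to_csv(ROOT / "results" / "odds_ratios.csv", index=False)

    rf = microassoc.rf_predict(
        table, labels, taxa, taxonomy=taxonomy, n_trees=cfg.rf.n_trees,
        n_iterations=cfg.rf.n_iterations, train_frac=cfg.rf.train_frac, seed=cfg.seed,
    )
    rf.roc.to_csv(ROOT / "results" / "rf_roc.csv", index=False)
    rf.importances.rename("importance").to_csv(ROOT / "results" / "rf_importances.csv")
    print(f"random forest on {len(taxa)} flagged families: "
          f"accuracy={rf.mean_accuracy:.3f}, AUC={rf.auc:.3f}")
    print(f"most informative families: {rf.importances.index[:3].tolist()}")


if __name__ == "__main__":
    main()
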