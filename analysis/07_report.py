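#!/usr/bin/env python
"""Assemble the stage-by-stage filter report from the analysis outputs."""

import json
from pathlib import Path

import pandas as pd

from anxmediate import io, pipeline

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"
CFG = Path(__file__).resolve().parent / "config.yaml"


def main() -> None:
    cfg = pipeline.load_config(CFG)
    pheno = pd.read_csv(RES / "phenotypes.csv")
    labels = pd.read_csv(RES / "labels.csv", index_col="mouse_id")["anxiety"]
    gwas = pd.read_csv(RES / "gwas.csv")
    hits = pd.read_csv(RES / "significant_snps.csv")
    fam = pd.read_csv(RES / "family_tests.csv")
    otu = pd.read_csv(RES / "otu_tests.csv")
    med = pd.read_csv(RES / "mediation.csv")
    genotypes_header = (RES / "sim" / "genotypes.tsv").open().readline()
    n_snps_in = len(genotypes_header.rstrip("\n").split("\t")) - 1

    report = {
        "seed": cfg.seed,
        "thresholds": cfg.thresholds.model_dump(),
        "stages": {
            "behavior": {"n_profiles": len(pheno)},
            "classify": {
                "n_HA": int((labels == "HA").sum()),
                "n_LA": int((labels == "LA").sum()),
            },
            "gwas": {
                "n_snps_in": n_snps_in,
                "n_snps_post_maf": len(gwas),
                "n_significant_snps": len(hits),
            },
            "microbiome": {
                "n_families_tested": len(fam),
                "n_families_significant": int(fam["significant"].sum()),
                "n_otus_tested": len(otu),
                "n_otus_significant": int(otu["significant"].sum()),
            },
            "mediation": {
                "n_pairs_screened": len(med),
                "n_pairs_significant": int(med["significant"].sum()),
                "n_mediator_taxa": int(med.loc[med["significant"], "taxon"].nunique()),
                "n_loci": int(med.loc[med["significant"], "locus"].nunique()),
            },
        },
    }
    io.write_json(report, RES / "report.json")
    md = pipeline.summarize(report)
    (RES / "report.md").write_text(md + "\n")
    print(md)


if __name__ == "__main__":
    main()
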