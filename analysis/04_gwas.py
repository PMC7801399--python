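#!/usr/bin/env python
"""Marker-wise chi-square association of anxiety group with strain alleles.

MAF-filters the genotype matrix (minor allele in >= 3 of 30 strains),
tests every SNP's mouse-level 2x2 allele x anxiety table, selects SNPs
below the calibrated threshold, maps them to genes by positional
containment and tests overlap with the human GWAS gene lists.
"""

from pathlib import Path

import pandas as pd

from anxmediate import genassoc, io, pipeline

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
CFG = Path(__file__).resolve().parent / "config.yaml"


def main() -> None:
    cfg = pipeline.load_config(CFG)
    G = io.read_genotypes(SIM / "genotypes.tsv")
    labels = pd.read_csv(ROOT / "results" / "labels.csv", index_col="mouse_id")["anxiety"]
    strain = pd.read_csv(ROOT / "results" / "phenotypes.csv", index_col="mouse_id")["strain"]

    Gf = genassoc.maf_filter(G)
    print(f"MAF filter: {G.n_snps} -> {Gf.n_snps} SNPs (minor allele in >= 3 strains)")
    assoc = genassoc.snp_anxiety_test(Gf, labels, strain)
    assoc.to_csv(ROOT / "results" / "gwas.csv", index=False)

    hits = genassoc.select_significant(assoc, alpha=cfg.thresholds.alpha_gwas)
    hits.to_csv(ROOT / "results" / "significant_snps.csv", index=False)
    print(f"significant SNPs at p < {cfg.thresholds.alpha_gwas:g}: {len(hits)}")

    genes = io.read_genes_bed(SIM / "genes.bed", zero_based=True)
    gene_hits, orphans = genassoc.map_snps_to_genes(hits, genes)
    gene_hits.to_csv(ROOT / "results" / "gene_hits.csv", index=False)
    mouse_genes = sorted(gene_hits["gene"].unique())
    print(f"genes containing a significant SNP: {len(mouse_genes)} "
          f"({len(orphans)} SNPs outside genes)")

    overlap = {}
    for f in sorted(SIM.glob("human_*.txt")):
        phenotype = f.stem.removeprefix("human_")
        hlist = io.read_gene_list(f)
        k, p = genassoc.overlap_test(mouse_genes, hlist, universe_size=len(genes))
        overlap[phenotype] = {"overlap": k, "p": p}
        print(f"  overlap with human {phenotype} genes: k={k}, hypergeometric p={p:.2e}")
    io.write_json(overlap, ROOT / "results" / "human_overlap.json")


if __name__ == "__main__":
    main()
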