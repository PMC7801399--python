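#!/usr/bin/env python
"""Simulate the study cohort and write every pipeline input to results/sim.

Generates ~450 mice across 30 inbred strains (4 cages each), a 134,593-SNP
strain-level genotype matrix in linkage blocks, a 5,761-OTU / 71-family
cage-shared relative-abundance table, gene models and human GWAS gene
lists — with a planted genotype -> microbiome -> anxiety causal chain whose
ground truth is written alongside the data.
"""

from pathlib import Path

from anxmediate import io, pipeline, synthdata

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
CFG = Path(__file__).resolve().parent / "config.yaml"


def main() -> None:
    cfg = pipeline.load_config(CFG)
    cohort = pipeline._simulate(cfg)
    OUT.mkdir(parents=True, exist_ok=True)

    io.write_genotypes(cohort.genotypes, OUT / "genotypes.tsv")
    io.write_abundance(cohort.abundance, cohort.taxonomy, OUT / "abundance.tsv")
    io.write_genes_bed(cohort.genes, OUT / "genes.bed")
    cohort.mice.to_csv(OUT / "mice.csv", index=False)
    for ph, genes in cohort.human_gene_lists.items():
        io.write_gene_list(genes, OUT / f"human_{ph}.txt")

    truth = cohort.truth
    io.write_json(
        {
            "true_label": truth.true_label.to_dict(),
            "causal_blocks": truth.causal_blocks,
            "causal_pattern": truth.causal_pattern.tolist(),
            "beta0": truth.beta0,
            "expected_p_ha": truth.expected_p_ha,
            "plans": {
                m: {"segments": p.segments, "speeds": p.speeds, "frame_rate": p.frame_rate}
                for m, p in cohort.plans.items()
            },
        },
        OUT / "ground_truth.json",
    )
    # one example tracking profile for inspection
    mid, prof = next(iter(cohort.profiles()))
    io.write_profile(prof, OUT / f"profile_{mid}.csv")

    n_ha = int((truth.true_label == "HA").sum())
    print(f"simulated {len(cohort.mice)} mice / {cohort.spec.n_strains} strains "
          f"({n_ha} truly high-anxiety), {cohort.genotypes.n_snps} SNPs, "
          f"{cohort.abundance.shape[1]} OTUs in {cohort.taxonomy.nunique()} families")
    print(f"planted mediator families: {sorted(truth.mediator_families())}")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
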