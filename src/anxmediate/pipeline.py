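"""End-to-end orchestration: simulate -> phenotype -> classify -> GWAS ->
microbiome -> mediation, driven by one validated configuration.

Each stage is a pure function of its inputs, the configuration and the
seed; the run report records every filter count (in the order the
analysis narrative presents them), the thresholds applied, the stage
seeds and a checksum per key table, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import anxclass, behavior, genassoc, io, mediation, microassoc, synthdata

__all__ = ["RunConfig", "PipelineResult", "load_config", "run_all", "summarize"]


class SimulateBlock(BaseModel):
    n_strains: int = 30
    mice_per_strain: tuple[int, int] | int = (7, 25)
    n_snps: int = 134_593
    n_taxa_families: int = 71
    n_otus: int = 5_761
    cages_per_strain: int = 4
    frame_rate: float = 30.0
    assay_duration: float = 300.0
    block_len: int = 50
    area_noise: float = 0.02
    effects: dict = Field(default_factory=dict)  # MediationEffects overrides


class InputsBlock(BaseModel):
    phenotypes: Optional[str] = None  # CSV: mouse_id, strain, cage + phenotype columns
    genotypes: Optional[str] = None  # strain x SNP TSV
    abundance: Optional[str] = None  # sample x OTU TSV with taxonomy header
    genes: Optional[str] = None  # BED4
    human_gene_lists: dict[str, str] = Field(default_factory=dict)


class Thresholds(BaseModel):
    alpha_gwas: float = 1e-13
    family_fdr: float = 0.1
    otu_fdr: float = 0.05
    logit_fdr: float = 0.01
    screen_p: float = 1e-9
    mediation_fdr: float = 0.05

    @model_validator(mode="after")
    def _positive(self):
        for name, v in self.model_dump().items():
            if v <= 0:
                raise ValueError(f"threshold {name} must be positive")
        return self


class BehaviorBlock(BaseModel):
    theta_hi: float = 0.95
    theta_lo: float = 0.05
    min_dwell: int = 3


class ConsensusBlock(BaseModel):
    k_max: int = 4
    n_resamples: int = 100
    subsample_frac: float = 0.8


class RFBlock(BaseModel):
    n_trees: int = 1000
    n_iterations: int = 100
    train_frac: float = 0.9


class MediationBlock(BaseModel):
    n_boot: int = 1000
    locus_window: int = 1_000_000
    cage_bootstrap: bool = False


class RunConfig(BaseModel):
    """Validated pipeline configuration (YAML-friendly)."""

    seed: int = 0
    simulate: Optional[SimulateBlock] = None
    inputs: Optional[InputsBlock] = None
    thresholds: Thresholds = Field(default_factory=Thresholds)
    behavior: BehaviorBlock = Field(default_factory=BehaviorBlock)
    consensus: ConsensusBlock = Field(default_factory=ConsensusBlock)
    rf: RFBlock = Field(default_factory=RFBlock)
    mediation: MediationBlock = Field(default_factory=MediationBlock)

    @model_validator(mode="after")
    def _has_data_source(self):
        if self.simulate is None:
            if self.inputs is None:
                raise ValueError("config needs either a 'simulate' block or an 'inputs' block")
            missing = [
                f for f in ("phenotypes", "genotypes", "abundance")
                if getattr(self.inputs, f) is None
            ]
            if missing:
                raise ValueError(f"inputs block missing required field(s): {missing}")
        return self


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


@dataclass
class PipelineResult:
    report: dict
    phenotypes: pd.DataFrame
    labels: pd.Series
    consensus: anxclass.ConsensusResult
    gwas: pd.DataFrame
    significant_snps: pd.DataFrame
    gene_hits: pd.DataFrame
    family_tests: pd.DataFrame
    otu_tests: pd.DataFrame
    odds_ratios: pd.DataFrame
    rf: Optional[microassoc.RFResult]
    mediation_results: pd.DataFrame
    cohort: Optional[synthdata.Cohort] = None


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(float_format="%.12g").encode()).hexdigest()[:16]


def _simulate(cfg: RunConfig):
    sim = cfg.simulate
    spec = synthdata.CohortSpec(
        n_strains=sim.n_strains,
        mice_per_strain=tuple(sim.mice_per_strain) if isinstance(sim.mice_per_strain, (list, tuple)) else sim.mice_per_strain,
        n_snps=sim.n_snps,
        n_taxa_families=sim.n_taxa_families,
        n_otus=sim.n_otus,
        cages_per_strain=sim.cages_per_strain,
        frame_rate=sim.frame_rate,
        assay_duration=sim.assay_duration,
        seed=cfg.seed,
    )
    effects = synthdata.MediationEffects(**sim.effects)
    return synthdata.gen_cohort(spec, effects=effects, block_len=sim.block_len)


def _extract_phenotypes(cohort: synthdata.Cohort, cfg: RunConfig) -> pd.DataFrame:
    rows = {}
    for mid, prof in cohort.profiles(area_noise=cfg.simulate.area_noise):
        pv = behavior.extract_phenotypes(
            prof,
            theta_hi=cfg.behavior.theta_hi,
            theta_lo=cfg.behavior.theta_lo,
            min_dwell=cfg.behavior.min_dwell,
        )
        rows[mid] = pv.as_array()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(behavior.PHENOTYPE_NAMES))
    df.index.name = "mouse_id"
    return df.join(cohort.mice.set_index("mouse_id")[["strain", "sex", "cage"]])


def run_all(config: RunConfig | dict | str | Path) -> PipelineResult:
    """Execute every stage in dependency order and assemble the run report."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    elif isinstance(config, dict):
        config = RunConfig(**config)
    cfg = config
    thr = cfg.thresholds
    report: dict = {"seed": cfg.seed, "thresholds": thr.model_dump(), "stages": {}}

    # ---- stage 1: inputs -------------------------------------------------
    cohort = None
    if cfg.simulate is not None:
        cohort = _simulate(cfg)
        pheno = _extract_phenotypes(cohort, cfg)
        abundance, taxonomy = cohort.abundance, cohort.taxonomy
        genotypes = cohort.genotypes
        genes = cohort.genes
        human_lists = cohort.human_gene_lists
        report["stages"]["simulate"] = {
            "n_mice": len(cohort.mice),
            "n_strains": cohort.spec.n_strains,
            "n_snps": genotypes.n_snps,
            "n_otus": abundance.shape[1],
            "n_families": int(taxonomy.nunique()),
            "n_cages": int(cohort.mice["cage"].nunique()),
        }
    else:
        inp = cfg.inputs
        pheno = pd.read_csv(inp.phenotypes, index_col="mouse_id")
        genotypes = io.read_genotypes(inp.genotypes)
        abundance, taxonomy = io.read_abundance(inp.abundance)
        genes = io.read_genes_bed(inp.genes) if inp.genes else None
        human_lists = {k: io.read_gene_list(v) for k, v in inp.human_gene_lists.items()}
        report["stages"]["inputs"] = {
            "n_mice": len(pheno),
            "n_snps": genotypes.n_snps,
            "n_otus": abundance.shape[1],
        }
    pheno_cols = list(behavior.PHENOTYPE_NAMES)
    report["stages"]["behavior"] = {
        "n_profiles": len(pheno),
        "phenotypes": pheno_cols,
        "checksum": _checksum(pheno[pheno_cols]),
    }

    # ---- stage 2: anxiety classification ---------------------------------
    cons = anxclass.consensus_cluster(
        pheno[pheno_cols].to_numpy(),
        k_max=cfg.consensus.k_max,
        n_resamples=cfg.consensus.n_resamples,
        subsample_frac=cfg.consensus.subsample_frac,
        seed=cfg.seed,
    )
    labels = anxclass.assign_anxiety(cons, pheno)
    gtests = anxclass.group_tests(pheno, labels)
    try:
        logit = anxclass.multivariate_logit(pheno, labels)
        logit_info = {"n_significant": int((logit["p"].iloc[1:] < 0.05).sum())}
    except (ValueError, RuntimeError) as e:  # separation is possible and reportable
        logit_info = {"error": str(e)}
    report["stages"]["classify"] = {
        "k": 2,
        "n_HA": int((labels == "HA").sum()),
        "n_LA": int((labels == "LA").sum()),
        "cdf_area": {str(k): cons.areas[k] for k in cons.ks},
        "delta_area": {str(k): cons.delta_areas[k] for k in cons.ks},
        "phenotypes_q_lt_0.01": int((gtests["q"] < 0.01).sum()),
        "multivariate_logit": logit_info,
    }

    # ---- stage 3: GWAS ----------------------------------------------------
    n_snps_in = genotypes.n_snps
    Gf = genassoc.maf_filter(genotypes)
    strain_of_mouse = pheno["strain"]
    assoc = genassoc.snp_anxiety_test(Gf, labels, strain_of_mouse)
    hits = genassoc.select_significant(assoc, alpha=thr.alpha_gwas)
    gene_hits = pd.DataFrame(columns=["gene", "chrom", "snp_id", "pos"])
    overlaps = {}
    if genes is not None and len(hits):
        gene_hits, orphans = genassoc.map_snps_to_genes(hits, genes)
        mouse_genes = sorted(gene_hits["gene"].unique())
        for ph_name, hlist in human_lists.items():
            k, p = genassoc.overlap_test(mouse_genes, hlist, universe_size=len(genes))
            overlaps[ph_name] = {"overlap": k, "p": p}
    report["stages"]["gwas"] = {
        "n_snps_in": n_snps_in,
        "n_snps_post_maf": Gf.n_snps,
        "maf_rule": "minor allele in >= 3 strains",
        "alpha": thr.alpha_gwas,
        "n_significant_snps": len(hits),
        "n_genes_hit": int(gene_hits["gene"].nunique()),
        "human_overlap": overlaps,
        "checksum": _checksum(assoc[["snp_id", "chi2", "p"]]),
    }

    # ---- stage 4: microbiome ---------------------------------------------
    fam_tests = microassoc.differential_abundance(
        abundance, labels, level="family", taxonomy=taxonomy, fdr=thr.family_fdr
    )
    otu_tests = microassoc.differential_abundance(
        abundance, labels, level="otu", fdr=thr.otu_fdr
    )
    sig_families = fam_tests.loc[fam_tests["significant"], "taxon"].tolist()
    odds = pd.DataFrame(columns=["taxon", "odds_ratio", "or_lo", "or_hi", "p", "q"])
    rf_res = None
    if sig_families:
        odds = microassoc.taxon_logistic(abundance, labels, sig_families, taxonomy=taxonomy)
        rf_res = microassoc.rf_predict(
            abundance,
            labels,
            sig_families,
            taxonomy=taxonomy,
            n_trees=cfg.rf.n_trees,
            n_iterations=cfg.rf.n_iterations,
            train_frac=cfg.rf.train_frac,
            seed=cfg.seed,
        )
    report["stages"]["microbiome"] = {
        "n_families_tested": len(fam_tests),
        "n_families_significant": len(sig_families),
        "family_fdr": thr.family_fdr,
        "n_otus_tested": len(otu_tests),
        "n_otus_significant": int(otu_tests["significant"].sum()),
        "otu_fdr": thr.otu_fdr,
        "significant_families": sig_families,
        "rf_accuracy": None if rf_res is None else rf_res.mean_accuracy,
        "rf_auc": None if rf_res is None else rf_res.auc,
        "rf_top_family": None if rf_res is None else rf_res.importances.index[0],
    }

    # ---- stage 5: mediation ----------------------------------------------
    fam_table = microassoc.family_abundance(abundance, taxonomy)
    med_df = pd.DataFrame()
    n_pairs = 0
    if len(hits) and sig_families:
        pairs = mediation.screen_pairs(
            Gf, fam_table, hits["snp_id"], sig_families, strain_of_mouse, p_threshold=thr.screen_p
        )
        n_pairs = len(pairs)
        cage = pheno["cage"] if "cage" in pheno.columns else None
        med_df = mediation.mediation_scan(
            pairs,
            Gf,
            fam_table,
            labels,
            strain_of_mouse,
            fdr=thr.mediation_fdr,
            n_boot=cfg.mediation.n_boot,
            seed=cfg.seed,
            locus_window=cfg.mediation.locus_window,
            cage_of_mouse=cage,
            cage_bootstrap=cfg.mediation.cage_bootstrap,
        )
    n_sig_pairs = int(med_df["significant"].sum()) if len(med_df) else 0
    report["stages"]["mediation"] = {
        "screen_p": thr.screen_p,
        "n_pairs_screened": n_pairs,
        "n_pairs_significant": n_sig_pairs,
        "mediation_fdr": thr.mediation_fdr,
        "n_mediator_taxa": int(med_df.loc[med_df["significant"], "taxon"].nunique()) if n_sig_pairs else 0,
        "n_loci": int(med_df.loc[med_df["significant"], "locus"].nunique()) if n_sig_pairs else 0,
        "n_snps_mediated": int(med_df.loc[med_df["significant"], "snp_id"].nunique()) if n_sig_pairs else 0,
    }

    return PipelineResult(
        report=report,
        phenotypes=pheno,
        labels=labels,
        consensus=cons,
        gwas=assoc,
        significant_snps=hits,
        gene_hits=gene_hits,
        family_tests=fam_tests,
        otu_tests=otu_tests,
        odds_ratios=odds,
        rf=rf_res,
        mediation_results=med_df,
        cohort=cohort,
    )


_STAGE_ROWS = [
    ("gwas", "n_snps_in", "n_snps_post_maf", "minor allele in >= 3 strains"),
    ("gwas", "n_snps_post_maf", "n_significant_snps", "chi-square p < alpha_gwas"),
    ("microbiome", "n_families_tested", "n_families_significant", "Mann-Whitney BH q < family_fdr"),
    ("microbiome", "n_otus_tested", "n_otus_significant", "Mann-Whitney BH q < otu_fdr"),
    ("mediation", "n_pairs_screened", "n_pairs_significant", "ACME bootstrap BH q < mediation_fdr"),
]


def summarize(report: dict) -> str:
    """Render the run report as a Markdown stage/filter summary table."""
    lines = [
        "| stage | input | surviving | rule |",
        "|---|---|---|---|",
    ]
    stages = report.get("stages", {})
    for stage, key_in, key_out, rule in _STAGE_ROWS:
        s = stages.get(stage, {})
        lines.append(f"| {stage} | {s.get(key_in, 0)} | {s.get(key_out, 0)} | {rule} |")
    cls = stages.get("classify", {})
    lines.append(
        f"| classify | {stages.get('behavior', {}).get('n_profiles', 0)} "
        f"| HA={cls.get('n_HA', 0)} / LA={cls.get('n_LA', 0)} | K=2 consensus clustering |"
    )
    return "\n".join(lines)
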