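"""Strain-panel SNP association with anxiety group membership.

Genotypes live at strain level (inbred panel: every mouse of a strain is
genetically identical).  Each mouse contributes its strain's allele at each
SNP, and a 2x2 chi-square test (allele class x anxiety group, mouse-level
counts, no continuity correction) is computed per SNP.  Significant SNPs
are mapped to genes by positional containment, and mouse candidate genes
are compared with human GWAS gene lists by an exact hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ALLELE_A",
    "ALLELE_B",
    "ALLELE_H",
    "ALLELE_N",
    "GenotypeMatrix",
    "maf_filter",
    "chi2_2x2",
    "snp_anxiety_test",
    "select_significant",
    "map_snps_to_genes",
    "overlap_test",
]

# integer allele codes used in the strain x SNP matrix
ALLELE_A = 0
ALLELE_B = 1
ALLELE_H = 2  # heterozygous call
ALLELE_N = 3  # missing call

_CODE_TO_CHAR = np.array(["A", "B", "H", "N"])
_CHAR_TO_CODE = {c: i for i, c in enumerate(_CODE_TO_CHAR)}


@dataclass
class GenotypeMatrix:
    """Strain-by-SNP biallelic genotype matrix with genomic positions.

    ``alleles`` is an int8 array (n_strains x n_snps) with codes
    ``ALLELE_A/B/H/N``; ``chrom`` and ``pos`` are per-SNP, positions
    1-based.
    """

    alleles: np.ndarray
    strains: list[str]
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.snp_ids = np.asarray(self.snp_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        ns, nm = self.alleles.shape
        if ns != len(self.strains):
            raise ValueError("allele rows must match strain names")
        if not (self.snp_ids.size == self.chrom.size == self.pos.size == nm):
            raise ValueError("per-SNP metadata must match allele columns")
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("strain names must be unique")

    @property
    def n_strains(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def subset_snps(self, mask_or_idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            alleles=self.alleles[:, mask_or_idx],
            strains=list(self.strains),
            snp_ids=self.snp_ids[mask_or_idx],
            chrom=self.chrom[mask_or_idx],
            pos=self.pos[mask_or_idx],
        )

    def allele_chars(self) -> np.ndarray:
        return _CODE_TO_CHAR[self.alleles]

    @staticmethod
    def codes_from_chars(chars) -> np.ndarray:
        arr = np.asarray(chars)
        out = np.empty(arr.shape, dtype=np.int8)
        for c, i in _CHAR_TO_CODE.items():
            out[arr == c] = i
        bad = ~np.isin(arr, _CODE_TO_CHAR)
        if bad.any():
            raise ValueError(f"invalid allele code(s): {np.unique(arr[bad])}")
        return out


def maf_filter(G: GenotypeMatrix, min_strains: int = 3) -> GenotypeMatrix:
    """Retain SNPs whose minor allele is carried by >= ``min_strains`` strains.

    H and N strain calls count toward neither allele.  Monomorphic SNPs
    (minor count 0) are always removed.  Idempotent.
    """
    n_a = np.count_nonzero(G.alleles == ALLELE_A, axis=0)
    n_b = np.count_nonzero(G.alleles == ALLELE_B, axis=0)
    minor = np.minimum(n_a, n_b)
    return G.subset_snps(minor >= min_strains)


def chi2_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray):
    """Pearson chi-square for 2x2 tables [[a, b], [c, d]], no continuity
    correction: ``n (ad - bc)^2 / (r1 r2 c1 c2)``.

    Tables with any zero margin get statistic 0 and p = 1.  Vectorized over
    arrays of tables.  Returns ``(chi2, p, zero_margin)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    zero_margin = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(zero_margin, 0.0, n * (a * d - b * c) ** 2 / np.where(zero_margin, 1.0, denom))
    p = np.where(zero_margin, 1.0, sps.chi2.sf(stat, df=1))
    return stat, p, zero_margin


def snp_anxiety_test(
    G: GenotypeMatrix,
    labels: pd.Series,
    strain_of_mouse: pd.Series,
) -> pd.DataFrame:
    """Per-SNP chi-square association of allele class with anxiety group.

    Each mouse contributes its strain's allele; mice whose strain call is
    H or N at a SNP are excluded from that SNP's table.

    Parameters
    ----------
    labels : Series indexed by mouse id with values "HA"/"LA".
    strain_of_mouse : Series indexed by mouse id giving the strain name.

    Returns
    -------
    DataFrame with snp_id, chrom, pos, the 2x2 counts
    (a=A&HA, b=A&LA, c=B&HA, d=B&LA), chi2, p and a zero-margin flag.
    """
    mice = labels.index
    strains = strain_of_mouse.reindex(mice)
    if strains.isna().any():
        missing = list(strains.index[strains.isna()][:3])
        raise ValueError(f"mice without a strain mapping: {missing}")
    strain_idx = pd.Index(G.strains).get_indexer(strains.to_numpy())
    if (strain_idx < 0).any():
        raise ValueError("some mice map to strains absent from the genotype matrix")

    M = G.alleles[strain_idx, :]  # n_mice x n_snps
    ha = (labels.to_numpy() == "HA")[:, None]
    is_a = M == ALLELE_A
    is_b = M == ALLELE_B
    a = np.count_nonzero(is_a & ha, axis=0)
    b = np.count_nonzero(is_a & ~ha, axis=0)
    c = np.count_nonzero(is_b & ha, axis=0)
    d = np.count_nonzero(is_b & ~ha, axis=0)
    stat, p, zero_margin = chi2_2x2(a, b, c, d)
    return pd.DataFrame(
        {
            "snp_id": G.snp_ids,
            "chrom": G.chrom,
            "pos": G.pos,
            "n_A_HA": a,
            "n_A_LA": b,
            "n_B_HA": c,
            "n_B_LA": d,
            "chi2": stat,
            "p": p,
            "zero_margin": zero_margin,
        }
    )


def select_significant(associations: pd.DataFrame, alpha: float = 1e-13) -> pd.DataFrame:
    """SNPs with p strictly below ``alpha`` (p == alpha is excluded)."""
    return associations.loc[associations["p"] < alpha].reset_index(drop=True)


def map_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign SNPs to every gene containing them (1-based inclusive ends).

    Parameters
    ----------
    snps : DataFrame with snp_id, chrom, pos columns.
    genes : DataFrame with name, chrom, start, end columns (1-based,
        inclusive on both ends).  Overlapping genes each receive the SNP.

    Returns
    -------
    (assignments, orphans)
        ``assignments`` has one row per (gene, SNP) containment;
        ``orphans`` lists SNPs falling in no gene.
    """
    if (genes["start"] > genes["end"]).any():
        bad = genes.loc[genes["start"] > genes["end"], "name"].iloc[0]
        raise ValueError(f"malformed gene interval (start > end): {bad}")
    rows = []
    assigned = np.zeros(len(snps), dtype=bool)
    pos = snps["pos"].to_numpy()
    chrom = snps["chrom"].to_numpy()
    for g in genes.itertuples(index=False):
        hit = (chrom == g.chrom) & (pos >= g.start) & (pos <= g.end)
        if hit.any():
            assigned |= hit
            for sid, p in zip(snps["snp_id"].to_numpy()[hit], pos[hit]):
                rows.append((g.name, g.chrom, sid, int(p)))
    assignments = pd.DataFrame(rows, columns=["gene", "chrom", "snp_id", "pos"])
    orphans = snps.loc[~assigned].reset_index(drop=True)
    return assignments, orphans


def overlap_test(
    mouse_genes, human_genes, universe_size: int
) -> tuple[int, float]:
    """Exact hypergeometric test of gene-set overlap.

    Symbols are matched case-insensitively.  Returns the overlap size k and
    ``P(X >= k)`` for X ~ Hypergeom(universe_size, |A|, |B|).
    """
    a = {str(g).upper() for g in mouse_genes}
    b = {str(g).upper() for g in human_genes}
    if universe_size < max(len(a), len(b)):
        raise ValueError("universe smaller than one of the gene sets")
    k = len(a & b)
    # P(X >= k) = sf(k - 1)
    p = float(sps.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, min(p, 1.0)
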