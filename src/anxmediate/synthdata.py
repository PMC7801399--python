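"""Synthetic cohort generator with planted ground truth.

Emulates every input of the genetics -> microbiome -> anxiety pipeline for
an inbred mouse panel: light/dark-box tracking profiles realizing planted
transition plans, a strain-level biallelic genotype matrix with linkage
blocks, a cage-shared OTU relative-abundance table with family taxonomy,
gene models and human GWAS gene lists.  The generative causal model is the
one the mediation analysis assumes:

* mediator (per cage c of strain s, planted family j):
  ``M_cj = alpha0 + alpha1_j * T_sj + sigma * z_cj`` where ``T_sj`` is the
  strain's allele code (0/1) at the causal block and z is cage noise;
* outcome (per mouse): ``P(HA) = Phi(beta0 + sum_j beta1*T_sj + beta2_j*M_cj)``;
* behavior: each mouse's transition plan is drawn from its label's
  phenotype regime (high-anxiety mice make fewer transitions and spend
  less time in the light).

Every stochastic draw flows from the single ``CohortSpec.seed``.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .behavior import TrackingProfile
from .genassoc import ALLELE_A, ALLELE_B, GenotypeMatrix

__all__ = [
    "BOX_WIDTH_MM",
    "BOX_LENGTH_MM",
    "CohortSpec",
    "MediationEffects",
    "TransitionPlan",
    "GroundTruth",
    "Cohort",
    "build_plan",
    "gen_tracking_profile",
    "gen_genotypes",
    "gen_gene_models",
    "gen_human_gene_lists",
    "gen_labeled_abundance",
    "gen_cohort",
]

# Light compartment footprint (20 cm x 40 cm); the opening to the dark
# compartment sits on the far y wall.
BOX_WIDTH_MM = 200.0
BOX_LENGTH_MM = 400.0

_AREA_LIGHT = 1.0
_AREA_PARTIAL = 0.3
_AREA_DARK = 0.0

_MIN_SEG_FRAMES = 5


@dataclass
class CohortSpec:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror the design of the source study: 30 strains with 7-25
    mice each (~450 mice), at least four independently sampled cages per
    strain, 134,593 SNPs, 5,761 OTUs in 71 bacterial families, and a 300 s
    light/dark assay.  The frame rate is a free parameter (30 frames/s by
    default).
    """

    n_strains: int = 30
    mice_per_strain: int | tuple[int, int] = (7, 25)
    n_snps: int = 134_593
    n_taxa_families: int = 71
    n_otus: int = 5_761
    cages_per_strain: int = 4
    frame_rate: float = 30.0
    assay_duration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_strains, self.n_snps, self.n_taxa_families, self.n_otus, self.cages_per_strain]
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.assay_duration <= 0 or self.frame_rate <= 0:
            raise ValueError("assay_duration and frame_rate must be positive")
        if isinstance(self.mice_per_strain, tuple):
            lo, hi = self.mice_per_strain
            if lo < 1 or hi < lo:
                raise ValueError("mice_per_strain range must satisfy 1 <= lo <= hi")
        elif self.mice_per_strain < 1:
            raise ValueError("mice_per_strain must be >= 1")
        if self.n_otus < self.n_taxa_families:
            raise ValueError("need at least one OTU per family")


@dataclass
class MediationEffects:
    """Planted effect sizes for the genotype -> microbiome -> anxiety chain.

    ``alpha1`` is the allele effect on the mediator family's log abundance
    (in cage-noise SD units when ``mediator_sd`` is 1); ``beta1`` and
    ``beta2`` are the probit-scale direct allele effect and the mediator
    effect on anxiety.  ``families`` pairs each planted family with the
    direction (+1/-1) of its abundance change in high-anxiety mice; the
    per-family signed effects are ``alpha1_j = dir * alpha1`` and
    ``beta2_j = dir * beta2`` so every planted allele is anxiogenic while
    family directions differ.

    The planted loci share a single anxiety-associated strain distribution
    pattern (SDP), one locus per mediator family on separate chromosomes.
    SDP multiplicity across unlinked loci is characteristic of small
    multiparental inbred panels, and a shared planted SDP gives the
    marker-wise association scan a well-defined target amid the chance
    strain-pattern alignments that a 30-strain panel inevitably produces.
    """

    alpha0: float = 0.0
    alpha1: float = 1.0
    mediator_sd: float = 0.7
    beta1: float = 0.3
    beta2: float = 0.45
    families: tuple[tuple[str, int], ...] = (
        ("Ruminococcaceae", +1),
        ("Bacteroidaceae", -1),
        ("Clostridiaceae", -1),
    )

    def __post_init__(self) -> None:
        for v in (self.alpha0, self.alpha1, self.mediator_sd, self.beta1, self.beta2):
            if not math.isfinite(v):
                raise ValueError("effect sizes must be finite")
        if self.mediator_sd < 0:
            raise ValueError("mediator_sd must be >= 0")
        for _, d in self.families:
            if d not in (-1, 1):
                raise ValueError("family direction must be +1 or -1")

    @property
    def n_pairs(self) -> int:
        return len(self.families)

    @property
    def mediated_fraction(self) -> float:
        """Mediated share of a planted allele's total probit-scale effect."""
        total = self.beta1 + self.alpha1 * self.beta2
        return 0.0 if total == 0 else (self.alpha1 * self.beta2) / total


@dataclass
class TransitionPlan:
    """A planted light/dark dwell schedule for one assay.

    ``segments`` is an ordered list of ``(phase, n_frames)`` with phase in
    {"light", "partial", "dark"}; a plan always starts in the light (mice
    are placed into the light compartment).  ``speeds`` gives the constant
    centroid speed (mm/s) for each light segment in order.
    """

    segments: list[tuple[str, int]]
    speeds: list[float]
    frame_rate: float

    def __post_init__(self) -> None:
        if not self.segments or self.segments[0][0] != "light":
            raise ValueError("a plan must start with a light segment")
        n_light = sum(1 for ph, _ in self.segments if ph == "light")
        if len(self.speeds) != n_light:
            raise ValueError("one speed per light segment required")
        for ph, n in self.segments:
            if ph not in ("light", "partial", "dark"):
                raise ValueError(f"unknown phase {ph!r}")
            if n < 1:
                raise ValueError("segments must span at least one frame")

    @property
    def n_frames(self) -> int:
        return sum(n for _, n in self.segments)

    # --- planted (ground-truth) phenotype values -----------------------
    @property
    def planted_counts(self) -> tuple[int, int]:
        """(n_full, n_partial) implied by the dwell schedule."""
        n_full = n_partial = 0
        last_major = None
        from_dark = False
        for ph, _ in self.segments:
            if ph == "light":
                last_major = "light"
                from_dark = False
            elif ph == "dark":
                if last_major == "light":
                    n_full += 1
                elif from_dark:
                    n_partial += 1
                last_major = "dark"
                from_dark = False
            else:
                from_dark = last_major == "dark"
        return n_full, n_partial

    @property
    def planted_time_light(self) -> float:
        return sum(n for ph, n in self.segments if ph == "light") / self.frame_rate

    @property
    def planted_latency(self) -> float:
        acc = 0
        for ph, n in self.segments:
            if ph == "dark":
                return acc / self.frame_rate
            acc += n
        return self.n_frames / self.frame_rate

    @property
    def planted_distance(self) -> float:
        """Exact polyline length of the planted light-phase path (mm)."""
        total = 0.0
        i = 0
        for ph, n in self.segments:
            if ph == "light":
                total += (n - 1) * self.speeds[i] / self.frame_rate
                i += 1
        return total


def _split_frames(total: int, parts: int, rng: np.random.Generator, min_seg: int = _MIN_SEG_FRAMES) -> list[int]:
    """Split ``total`` frames into ``parts`` chunks of at least ``min_seg``."""
    if parts == 0:
        if total != 0:
            raise ValueError("frames left over with no segment to hold them")
        return []
    if total < parts * min_seg:
        raise ValueError(f"cannot fit {parts} segments of >= {min_seg} frames into {total}")
    w = rng.dirichlet(np.full(parts, 2.0))
    extra = total - parts * min_seg
    alloc = np.floor(w * extra).astype(int)
    short = extra - alloc.sum()
    order = np.argsort(-(w * extra - alloc))
    alloc[order[:short]] += 1
    return (alloc + min_seg).tolist()


def build_plan(
    n_full: int,
    n_partial: int,
    time_light_s: float,
    speed_mm_s: float,
    frame_rate: float,
    duration_s: float,
    rng: np.random.Generator,
    latency_s: float | None = None,
    end_in_light: bool | None = None,
) -> TransitionPlan:
    """Construct a random dwell schedule realizing the requested counts.

    The plan starts in the light, makes exactly ``n_full`` whole-body
    light->dark transitions and ``n_partial`` dark->partial->dark
    excursions, spends ``time_light_s`` seconds fully in the light
    (``latency_s`` of them before the first transition, when given), and
    pads to exactly ``duration_s``.  Raises ``ValueError`` when the
    requested schedule needs more frames than the assay provides.
    """
    total = round(duration_s * frame_rate)
    if n_full == 0:
        if n_partial > 0:
            raise ValueError("partial transitions require a dark phase (n_full >= 1)")
        return TransitionPlan([("light", total)], [speed_mm_s], frame_rate)

    if end_in_light is None:
        end_in_light = bool(rng.random() < 0.4)
    n_light = n_full + (1 if end_in_light else 0)
    light_frames = round(time_light_s * frame_rate)

    partials_per_dark = rng.multinomial(n_partial, np.full(n_full, 1.0 / n_full))
    partial_frames_each = rng.integers(_MIN_SEG_FRAMES, 31, size=n_partial)
    partial_total = int(partial_frames_each.sum())
    n_dark_segs = n_full + n_partial  # each partial splits a dark run
    dark_total = total - light_frames - partial_total
    if dark_total < n_dark_segs * _MIN_SEG_FRAMES:
        raise ValueError("plan requires more frames than the assay provides")

    if latency_s is not None:
        lat_frames = round(latency_s * frame_rate)
        lat_frames = int(np.clip(lat_frames, _MIN_SEG_FRAMES, light_frames - (n_light - 1) * _MIN_SEG_FRAMES))
        rest = _split_frames(light_frames - lat_frames, n_light - 1, rng) if n_light > 1 else []
        if n_light == 1 and light_frames != lat_frames:
            lat_frames = light_frames
        light_allocs = [lat_frames] + rest
    else:
        light_allocs = _split_frames(light_frames, n_light, rng)
    dark_allocs = _split_frames(dark_total, n_dark_segs, rng)

    segments: list[tuple[str, int]] = []
    speeds: list[float] = []
    d_idx = 0
    p_idx = 0
    for i in range(n_full):
        segments.append(("light", light_allocs[i]))
        speeds.append(float(speed_mm_s))
        # dark run i, interleaved with its partial excursions
        segments.append(("dark", dark_allocs[d_idx]))
        d_idx += 1
        for _ in range(int(partials_per_dark[i])):
            segments.append(("partial", int(partial_frames_each[p_idx])))
            p_idx += 1
            segments.append(("dark", dark_allocs[d_idx]))
            d_idx += 1
    if end_in_light:
        segments.append(("light", light_allocs[n_full]))
        speeds.append(float(speed_mm_s))
    return TransitionPlan(segments, speeds, frame_rate)


def _light_walk(
    n: int, step: float, rng: np.random.Generator, start: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Constant-step persistent random walk confined to the light box."""
    x = np.empty(n)
    y = np.empty(n)
    cx, cy = start
    x[0], y[0] = cx, cy
    heading = rng.uniform(0, 2 * math.pi)
    lo, hix, hiy = 1.0, BOX_WIDTH_MM - 1.0, BOX_LENGTH_MM - 1.0
    for i in range(1, n):
        heading += rng.normal(0.0, 0.5)
        nx = cx + step * math.cos(heading)
        ny = cy + step * math.sin(heading)
        while not (lo <= nx <= hix and lo <= ny <= hiy):
            heading = rng.uniform(0, 2 * math.pi)
            nx = cx + step * math.cos(heading)
            ny = cy + step * math.sin(heading)
        cx, cy = nx, ny
        x[i], y[i] = cx, cy
    return x, y


def gen_tracking_profile(
    plan: TransitionPlan,
    spec: CohortSpec | None = None,
    noise_sd: float = 0.0,
    area_noise: float = 0.0,
    rng: np.random.Generator | int | None = None,
    mouse_id: str = "",
) -> TrackingProfile:
    """Materialize a tracking profile realizing a planted plan.

    Light frames carry area fraction ~1, partial frames ~0.3, dark frames
    ~0; ``area_noise`` (sub-threshold, keep it below 0.05) perturbs these
    without crossing the state thresholds.  The centroid follows a
    constant-speed persistent random walk inside the 200 mm x 400 mm light
    compartment during light phases, sits at the opening during partial
    phases, and is NaN in the dark.  ``noise_sd`` adds Gaussian mm jitter
    to the centroid (0 keeps the planted path length exact).
    """
    if spec is not None:
        max_frames = round(spec.assay_duration * spec.frame_rate)
        if plan.n_frames > max_frames:
            raise ValueError("plan requires more frames than the assay provides")
    rng = np.random.default_rng(rng)
    fr = plan.frame_rate
    n = plan.n_frames
    area = np.empty(n)
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    opening = (BOX_WIDTH_MM / 2.0, BOX_LENGTH_MM - 2.0)

    pos = 0
    light_idx = 0
    first_light = True
    for ph, seg_n in plan.segments:
        sl = slice(pos, pos + seg_n)
        if ph == "light":
            area[sl] = _AREA_LIGHT - rng.uniform(0.0, area_noise, seg_n) if area_noise > 0 else _AREA_LIGHT
            start = (
                (BOX_WIDTH_MM / 2.0, BOX_LENGTH_MM / 2.0)
                if first_light
                else (opening[0] + rng.uniform(-20, 20), opening[1] - rng.uniform(5, 20))
            )
            step = plan.speeds[light_idx] / fr
            x[sl], y[sl] = _light_walk(seg_n, step, rng, start)
            light_idx += 1
            first_light = False
        elif ph == "partial":
            area[sl] = _AREA_PARTIAL + (rng.uniform(-area_noise, area_noise, seg_n) if area_noise > 0 else 0.0)
            x[sl], y[sl] = opening
        else:
            area[sl] = _AREA_DARK + (rng.uniform(0.0, area_noise, seg_n) if area_noise > 0 else 0.0)
        pos += seg_n

    if noise_sd > 0:
        vis = np.isfinite(x)
        x[vis] = np.clip(x[vis] + rng.normal(0, noise_sd, vis.sum()), 0, BOX_WIDTH_MM)
        y[vis] = np.clip(y[vis] + rng.normal(0, noise_sd, vis.sum()), 0, BOX_LENGTH_MM)

    t = np.arange(n) / fr
    return TrackingProfile(t=t, area_fraction=area, x=x, y=y, frame_rate=fr, mouse_id=mouse_id)


def gen_genotypes(
    spec: CohortSpec,
    block_len: int = 50,
    n_chromosomes: int = 20,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Strain-by-SNP genotypes organized in linkage blocks.

    Adjacent SNPs are copied in blocks of ``block_len`` identical strain
    partitions, mimicking the long identical-by-descent haplotype blocks of
    an inbred panel; each block lies on a single chromosome and positions
    increase strictly within chromosomes.  Returns the matrix and the
    per-SNP block id.
    """
    if block_len <= 0:
        raise ValueError(f"block_len must be positive, got {block_len}")
    if spec.n_strains < 2:
        raise ValueError("need at least two strains")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n_snps, n_strains = spec.n_snps, spec.n_strains
    n_blocks = math.ceil(n_snps / block_len)

    # one strain partition per block; allele-B count uniform over 0..n_strains
    n_b = rng.integers(0, n_strains + 1, size=n_blocks)
    patterns = np.zeros((n_strains, n_blocks), dtype=np.int8)
    for j in range(n_blocks):
        carriers = rng.choice(n_strains, size=n_b[j], replace=False)
        patterns[carriers, j] = ALLELE_B

    block_ids = np.repeat(np.arange(n_blocks), block_len)[:n_snps]
    alleles = patterns[:, block_ids]

    chrom_of_block = (np.arange(n_blocks) * n_chromosomes) // n_blocks
    chrom = np.array([f"chr{c + 1}" for c in chrom_of_block[block_ids]])
    pos = np.empty(n_snps, dtype=np.int64)
    gaps = rng.integers(500, 20_000, size=n_snps)
    for c in range(n_chromosomes):
        m = chrom == f"chr{c + 1}"
        pos[m] = np.cumsum(gaps[m])
    snp_ids = np.array([f"SNP{i:06d}" for i in range(n_snps)])
    strains = [f"CC{i + 1:03d}" for i in range(n_strains)]
    G = GenotypeMatrix(alleles=alleles, strains=strains, snp_ids=snp_ids, chrom=chrom, pos=pos)
    return G, block_ids


def gen_gene_models(
    G: GenotypeMatrix,
    rng: np.random.Generator,
    n_genes: int = 800,
    anchor_snps: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gene intervals (1-based inclusive) anchored on SNP positions.

    Each gene is placed around a sampled SNP so a realistic share of SNPs
    falls inside genes; ``anchor_snps`` forces specific SNP indices (e.g.
    planted causal SNPs) to be covered, those genes coming first.
    """
    anchors = list(anchor_snps) if anchor_snps is not None else []
    free = rng.choice(G.n_snps, size=max(0, n_genes - len(anchors)), replace=False)
    all_anchors = np.concatenate([np.asarray(anchors, dtype=int), free]).astype(int)
    rows = []
    for i, si in enumerate(all_anchors):
        up = int(rng.integers(1_000, 40_000))
        down = int(rng.integers(1_000, 40_000))
        start = max(1, int(G.pos[si]) - up)
        rows.append((f"Gene{i + 1:04d}", str(G.chrom[si]), start, int(G.pos[si]) + down))
    return pd.DataFrame(rows, columns=["name", "chrom", "start", "end"])


def gen_human_gene_lists(
    genes: pd.DataFrame,
    rng: np.random.Generator,
    causal_genes: list[str] | None = None,
    phenotypes: tuple[str, ...] = ("depression", "neuroticism", "adhd", "feeling_nervous"),
    list_size: int = 60,
) -> dict[str, list[str]]:
    """Human GWAS gene lists (uppercase symbols), one per phenotype.

    The first phenotype's list is enriched for the planted causal genes so
    the hypergeometric overlap test has a true positive to find.
    """
    pool = genes["name"].tolist()
    out: dict[str, list[str]] = {}
    for i, ph in enumerate(phenotypes):
        picks = list(rng.choice(pool, size=min(list_size, len(pool)), replace=False))
        if i == 0 and causal_genes:
            picks = list(dict.fromkeys(causal_genes + picks))[:list_size]
        out[ph] = [g.upper() for g in picks]
    return out


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification."""

    true_label: pd.Series  # mouse_id -> "HA"/"LA"
    planted_phenotypes: pd.DataFrame  # per-mouse n_full, n_partial, time_light, latency, distance
    causal_blocks: list[dict]  # per planted pair: block_id, snp_ids, family, direction, true_acme
    causal_pattern: np.ndarray  # shared strain distribution pattern (allele codes)
    cage_mediators: pd.DataFrame  # cage x planted family latent mediator values
    beta0: float
    effects: MediationEffects
    expected_p_ha: float  # probit-implied marginal P(HA)

    def causal_snp_ids(self) -> set[str]:
        return {s for blk in self.causal_blocks for s in blk["snp_ids"]}

    def mediator_families(self) -> set[str]:
        return {blk["family"] for blk in self.causal_blocks}

    def is_planted_signature(self, pattern: np.ndarray, taxon: str) -> bool:
        """Whether a discovered (strain pattern, taxon) pair was planted.

        All planted loci carry one shared strain distribution pattern, so
        SNPs with that pattern are statistically interchangeable; a
        mediation discovery is true when its pattern matches the planted
        one and the taxon is a planted mediator family.
        """
        return bool(np.array_equal(pattern, self.causal_pattern)) and taxon in self.mediator_families()


@dataclass
class Cohort:
    """A fully simulated cohort: inputs plus planted truth."""

    spec: CohortSpec
    mice: pd.DataFrame  # mouse_id, strain, sex, cage
    genotypes: GenotypeMatrix
    block_ids: np.ndarray
    abundance: pd.DataFrame  # mouse x OTU relative abundances
    taxonomy: pd.Series  # OTU -> family
    plans: dict[str, TransitionPlan]
    genes: pd.DataFrame
    human_gene_lists: dict[str, list[str]]
    truth: GroundTruth

    def profiles(self, noise_sd: float = 0.0, area_noise: float = 0.02):
        """Yield (mouse_id, TrackingProfile), deterministically seeded."""
        for mid, plan in self.plans.items():
            child = np.random.default_rng((self.spec.seed, zlib.crc32(mid.encode())))
            yield mid, gen_tracking_profile(
                plan, self.spec, noise_sd=noise_sd, area_noise=area_noise, rng=child, mouse_id=mid
            )

    def family_abundance(self) -> pd.DataFrame:
        return self.abundance.T.groupby(self.taxonomy).sum().T


def _planted_acme(effects: MediationEffects, j: int, beta0: float) -> float:
    """Exact population ACME transmitted through planted family j.

    All planted loci share one treatment pattern T, so for the pair-j
    contrast the other mediators follow T; the Gaussian mediator +
    probit outcome composition then has the closed form
    ``E[Phi(mu + s Z)] = Phi(mu / sqrt(1 + s^2))`` per arm.
    """
    fams = effects.families
    a1 = [d * effects.alpha1 for _, d in fams]
    b2 = [d * effects.beta2 for _, d in fams]
    sig2 = effects.mediator_sd**2
    s = math.sqrt(1.0 + sum(b2[k] ** 2 * sig2 for k in range(len(fams))))
    vals = []
    for t in (0, 1):
        c = beta0 + effects.beta1 * t
        for k in range(len(fams)):
            if k != j:
                c += b2[k] * (effects.alpha0 + a1[k] * t)
        hi = ndtr((c + b2[j] * (effects.alpha0 + a1[j])) / s)
        lo = ndtr((c + b2[j] * effects.alpha0) / s)
        vals.append(hi - lo)
    return float(np.mean(vals))


def _expected_p_ha(effects: MediationEffects, beta0: float) -> float:
    fams = effects.families
    a1 = [d * effects.alpha1 for _, d in fams]
    b2 = [d * effects.beta2 for _, d in fams]
    sig2 = effects.mediator_sd**2
    s = math.sqrt(1.0 + sum(v**2 * sig2 for v in b2))
    vals = []
    for t in (0, 1):
        c = beta0 + effects.beta1 * t + sum(b2[k] * (effects.alpha0 + a1[k] * t) for k in range(len(fams)))
        vals.append(ndtr(c / s))
    return float(np.mean(vals))


# Phenotype regimes: (mean, sd) per label, directions matching the
# light-avoidance readout (high anxiety = less light time, fewer
# transitions, shorter latency, slower exploration).
_REGIMES = {
    "HA": dict(n_full=(1, 2.0), n_partial=8.0, time_light=(55.0, 15.0, 20.0, 110.0),
               latency=(10.0, 4.0, 2.0, 30.0), speed=(45.0, 7.0, 20.0)),
    "LA": dict(n_full=(4, 6.0), n_partial=20.0, time_light=(130.0, 25.0, 60.0, 240.0),
               latency=(30.0, 10.0, 5.0, 80.0), speed=(80.0, 10.0, 30.0)),
}


def _draw_plan(label: str, spec: CohortSpec, rng: np.random.Generator) -> TransitionPlan:
    r = _REGIMES[label]
    base, lam = r["n_full"]
    n_full = int(base + rng.poisson(lam))
    n_partial = int(rng.poisson(r["n_partial"]))
    m, sd, lo, hi = r["time_light"]
    time_light = float(np.clip(rng.normal(m, sd), lo, hi))
    m, sd, lo, hi = r["latency"]
    latency = float(np.clip(rng.normal(m, sd), lo, min(hi, 0.6 * time_light)))
    m, sd, lo = r["speed"]
    speed = float(max(lo, rng.normal(m, sd)))
    for _ in range(20):
        try:
            return build_plan(
                n_full, n_partial, time_light, speed, spec.frame_rate,
                spec.assay_duration, rng, latency_s=latency,
            )
        except ValueError:
            # schedule did not fit; relax the busiest components and retry
            n_partial = max(0, n_partial - 2)
            n_full = max(1, n_full - 1)
            time_light = max(20.0, 0.9 * time_light)
    raise RuntimeError("could not fit a plan into the assay duration")


def _pick_causal_blocks(
    patterns: np.ndarray,
    chrom_of_block: np.ndarray,
    n_pairs: int,
    rng: np.random.Generator,
) -> tuple[list[int], np.ndarray]:
    """Choose planted loci and the shared causal strain pattern.

    One balanced strain distribution pattern is drawn (allele-B share near
    one half) and assigned to ``n_pairs`` blocks on distinct chromosomes.
    Returns the chosen block indices and the shared pattern.
    """
    n_strains, n_blocks = patterns.shape
    counts = (patterns == ALLELE_B).sum(axis=0)
    lo, hi = int(0.4 * n_strains), int(0.6 * n_strains)
    candidates = np.flatnonzero((counts >= lo) & (counts <= hi))
    rng.shuffle(candidates)
    chosen: list[int] = []
    used_chroms: set = set()
    for b in candidates:
        c = chrom_of_block[b]
        if c in used_chroms:
            continue
        chosen.append(int(b))
        used_chroms.add(c)
        if len(chosen) == n_pairs:
            break
    else:
        raise RuntimeError("not enough balanced blocks on distinct chromosomes")
    shared = patterns[:, chosen[0]].copy()
    return chosen, shared


def gen_cohort(
    spec: CohortSpec,
    effects: MediationEffects | None = None,
    block_len: int = 50,
    n_chromosomes: int = 20,
    n_genes: int = 800,
) -> Cohort:
    """Simulate a complete cohort with planted mediation ground truth."""
    effects = effects or MediationEffects()
    rng = np.random.default_rng(spec.seed)

    # --- mice, cages ----------------------------------------------------
    strains = [f"CC{i + 1:03d}" for i in range(spec.n_strains)]
    if isinstance(spec.mice_per_strain, tuple):
        lo, hi = spec.mice_per_strain
        counts = rng.integers(lo, hi + 1, size=spec.n_strains)
    else:
        counts = np.full(spec.n_strains, spec.mice_per_strain)
    rows = []
    for s, cnt in zip(strains, counts):
        for k in range(cnt):
            rows.append((f"{s}_m{k + 1:02d}", s, "F" if rng.random() < 0.5 else "M", f"{s}_c{k % spec.cages_per_strain + 1}"))
    mice = pd.DataFrame(rows, columns=["mouse_id", "strain", "sex", "cage"])

    # --- genotypes and causal blocks ------------------------------------
    G, block_ids = gen_genotypes(spec, block_len=block_len, n_chromosomes=n_chromosomes, rng=rng)
    n_blocks = int(block_ids.max()) + 1
    first_snp_of_block = np.searchsorted(block_ids, np.arange(n_blocks))
    patterns = G.alleles[:, first_snp_of_block]
    chrom_of_block = G.chrom[first_snp_of_block]
    causal_block_ids, shared_pattern = _pick_causal_blocks(patterns, chrom_of_block, effects.n_pairs, rng)
    # stamp the shared SDP onto every planted locus
    for bid in causal_block_ids:
        G.alleles[:, block_ids == bid] = shared_pattern[:, None]
        patterns[:, bid] = shared_pattern

    # --- cage-level mediators -------------------------------------------
    strain_index = {s: i for i, s in enumerate(strains)}
    cages = mice[["cage", "strain"]].drop_duplicates().set_index("cage")["strain"]
    fam_names = [f for f, _ in effects.families]
    med = pd.DataFrame(index=cages.index, columns=fam_names, dtype=float)
    T_of_strain = {s: int(shared_pattern[strain_index[s]] == ALLELE_B) for s in strains}
    for j, (fam, d) in enumerate(effects.families):
        a1j = d * effects.alpha1
        for cage, s in cages.items():
            med.loc[cage, fam] = effects.alpha0 + a1j * T_of_strain[s] + effects.mediator_sd * rng.normal()

    # --- probit outcome --------------------------------------------------
    b2 = [d * effects.beta2 for _, d in effects.families]
    beta0 = -(
        0.5 * effects.beta1
        + sum(b2[j] * (effects.alpha0 + (effects.families[j][1] * effects.alpha1) * 0.5) for j in range(effects.n_pairs))
    )
    t_vec = mice["strain"].map(T_of_strain).to_numpy(dtype=float)
    eta = beta0 + effects.beta1 * t_vec
    for j, (fam, _) in enumerate(effects.families):
        eta += b2[j] * mice["cage"].map(med[fam]).to_numpy(dtype=float)
    labels = np.where(rng.standard_normal(len(mice)) < eta, "HA", "LA")
    true_label = pd.Series(labels, index=mice["mouse_id"], name="true_label")

    # --- behavior plans ---------------------------------------------------
    plans: dict[str, TransitionPlan] = {}
    planted_rows = []
    for mid, lab in true_label.items():
        plan = _draw_plan(lab, spec, rng)
        plans[mid] = plan
        nf, npart = plan.planted_counts
        planted_rows.append((mid, nf, npart, plan.planted_time_light, plan.planted_latency, plan.planted_distance))
    planted = pd.DataFrame(
        planted_rows,
        columns=["mouse_id", "n_full", "n_partial", "time_light", "latency", "distance"],
    ).set_index("mouse_id")

    # --- abundance table --------------------------------------------------
    generic = [f"Family{i + 1:02d}" for i in range(spec.n_taxa_families - len(fam_names))]
    families = fam_names + generic
    # planted families get a guaranteed OTU contingent; the rest spread by
    # Dirichlet weights with one OTU per family minimum
    per_planted = max(5, spec.n_otus // len(families))
    n_generic_otus = spec.n_otus - per_planted * len(fam_names)
    fam_w = rng.dirichlet(np.full(len(generic), 0.6))
    fam_of_otu = np.concatenate([
        np.repeat(np.arange(len(fam_names)), per_planted),
        len(fam_names) + np.arange(len(generic)),
        len(fam_names) + rng.choice(len(generic), size=n_generic_otus - len(generic), p=fam_w),
    ])
    rng.shuffle(fam_of_otu)
    otu_ids = np.array([f"OTU{i + 1:05d}" for i in range(spec.n_otus)])
    taxonomy = pd.Series([families[f] for f in fam_of_otu], index=otu_ids, name="family")

    fam_base = rng.normal(0.0, 1.2, size=len(families))
    # planted families sit at a typical base share so their fold-changes do
    # not dominate the compositional denominator
    fam_base[: len(fam_names)] = 0.0
    otu_base = fam_base[fam_of_otu] + rng.normal(0.0, 1.0, size=spec.n_otus)
    bg_sd = 0.3  # cage-level log-abundance noise for non-planted families
    cage_list = med.index.to_list()
    logA = np.tile(otu_base, (len(cage_list), 1))
    fam_idx_of = {f: i for i, f in enumerate(families)}
    for ci, cage in enumerate(cage_list):
        shift = np.zeros(len(families))
        for j, fam in enumerate(fam_names):
            shift[fam_idx_of[fam]] = med.loc[cage, fam]
        for f in range(len(fam_names), len(families)):
            shift[f] = bg_sd * rng.normal()
        logA[ci] += shift[fam_of_otu]
    cage_profiles = np.exp(logA)
    neg = cage_profiles < 0
    if neg.any():  # defensive: log-normal construction cannot go negative
        warnings.warn("negative abundances encountered; renormalizing")
        cage_profiles[neg] = 0.0
    cage_profiles /= cage_profiles.sum(axis=1, keepdims=True)
    cage_pos = {c: i for i, c in enumerate(cage_list)}
    rows_idx = mice["cage"].map(cage_pos).to_numpy()
    abundance = pd.DataFrame(cage_profiles[rows_idx], index=mice["mouse_id"], columns=otu_ids)

    # --- gene models + human lists ---------------------------------------
    anchor = first_snp_of_block[causal_block_ids]
    genes = gen_gene_models(G, rng, n_genes=n_genes, anchor_snps=anchor)
    causal_genes = genes["name"].iloc[: effects.n_pairs].tolist()
    human_lists = gen_human_gene_lists(genes, rng, causal_genes=causal_genes)

    causal_blocks = []
    for j, (fam, d) in enumerate(effects.families):
        bid = causal_block_ids[j]
        snp_mask = block_ids == bid
        causal_blocks.append(
            {
                "block_id": int(bid),
                "snp_ids": list(G.snp_ids[snp_mask]),
                "family": fam,
                "direction": int(d),
                "alpha1": d * effects.alpha1,
                "beta1": effects.beta1,
                "beta2": d * effects.beta2,
                "gene": causal_genes[j],
                "true_acme": _planted_acme(effects, j, beta0),
            }
        )
    truth = GroundTruth(
        true_label=true_label,
        planted_phenotypes=planted,
        causal_blocks=causal_blocks,
        causal_pattern=shared_pattern.copy(),
        cage_mediators=med,
        beta0=beta0,
        effects=effects,
        expected_p_ha=_expected_p_ha(effects, beta0),
    )
    return Cohort(
        spec=spec,
        mice=mice,
        genotypes=G,
        block_ids=block_ids,
        abundance=abundance,
        taxonomy=taxonomy,
        plans=plans,
        genes=genes,
        human_gene_lists=human_lists,
        truth=truth,
    )


def gen_labeled_abundance(
    labels: pd.Series,
    shifts: dict[str, float],
    n_families: int = 71,
    n_otus: int = 400,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Abundance table with direct label-linked family shifts.

    A lighter-weight generator for association power studies: each sample
    gets independent log-normal OTU abundances, and every family named in
    ``shifts`` has its log abundance moved by the stated number of
    within-group SDs in high-anxiety samples.  Negative planted abundances
    cannot arise on the log scale; if an additive planting scheme ever
    produces one it is renormalized with a warning rather than clipped.
    """
    rng = np.random.default_rng(seed)
    fam_names = list(shifts) + [f"Family{i + 1:02d}" for i in range(n_families - len(shifts))]
    fam_of_otu = np.concatenate([
        np.arange(n_families),
        rng.choice(n_families, size=n_otus - n_families),
    ])
    otu_ids = np.array([f"OTU{i + 1:05d}" for i in range(n_otus)])
    taxonomy = pd.Series([fam_names[f] for f in fam_of_otu], index=otu_ids, name="family")
    otu_base = rng.normal(0.0, 1.0, size=n_otus)
    ha = (labels.to_numpy() == "HA").astype(float)
    logA = np.tile(otu_base, (len(labels), 1))
    fam_noise = rng.normal(0.0, 1.0, size=(len(labels), n_families))
    shift_vec = np.zeros(n_families)
    for i, f in enumerate(shifts):
        shift_vec[i] = shifts[f]
    fam_effect = fam_noise + ha[:, None] * shift_vec[None, :]
    logA += fam_effect[:, fam_of_otu]
    A = np.exp(logA)
    A /= A.sum(axis=1, keepdims=True)
    return pd.DataFrame(A, index=labels.index, columns=otu_ids), taxonomy
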