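# Methods

`anxmediate` implements an end-to-end inference chain for a Collaborative
Cross (CC) style mouse panel: light/dark-box behavior phenotyping,
consensus-clustering anxiety classification, marker-wise genetic
association, microbiome association and prediction, and causal mediation
linking the three layers.  Because the original raw data (videos, UNC
genotype files, 16S profiles) are not bundled, a first-class synthetic
cohort generator reproduces the statistical structure of every input with
planted ground truth, and the test suite validates each stage against that
truth or against independent closed-form oracles.

## Behavior phenotyping

A tracked mouse is summarized per frame by the fraction of its body
visible in the light compartment plus its centroid (mm) at a fixed frame
rate (default 30 frames/s, configurable; the assay is 300 s and the light
box is 200 mm x 400 mm).  Frames are thresholded into LIGHT
(`area >= theta_hi`, default 0.95), DARK (`<= theta_lo`, default 0.05) and
PARTIAL states; runs shorter than `min_dwell` frames (default 3, i.e.
0.1 s at 30 fps) are merged into the preceding state to suppress
segmentation flicker, with the opening run taken at face value.  The state
machine counts a *full transition* whenever DARK is reached after LIGHT
was the most recent major state (PARTIAL passages allowed), and a
*partial transition* for every DARK -> PARTIAL -> DARK excursion that never
reaches LIGHT.

The seven phenotypes and their conventions:

| phenotype | definition | unit |
|---|---|---|
| `time_light` | frames with `area >= 0.5` / frame rate (majority-of-body rule, so PARTIAL frames split sensibly) | s |
| `n_full_transitions` | state machine, above | count |
| `n_partial_transitions` | state machine, above | count |
| `distance_light` | summed centroid displacement over frame pairs fully in LIGHT (only the light compartment is filmed) | mm |
| `avg_speed` | `distance_light` / time in LIGHT state | mm/s |
| `avg_time_light` | `time_light` / number of LIGHT visits (initial placement counts as visit 1) | s |
| `latency_first_transition` | time of first entry into DARK; the full assay duration when the mouse never leaves the light (flag-worthy but well-defined) | s |

Whole-body vs partial-body thresholds are not quantified in the underlying
assay description, so `theta_hi`/`theta_lo` are configurable and recorded
in run metadata.

## Synthetic cohort generator

The generator emulates the study design: 30 strains, 7-25 mice per strain
(~450-500 mice), at least four independently sampled cages per strain,
134,593 SNPs, 5,761 OTUs in 71 bacterial families, 300 s assays.  Sex is
generated but carries no effect.

**Genotypes.** Strain-level biallelic calls are drawn in linkage blocks of
50 SNPs sharing one strain partition (allele-B count uniform over
0..30), with positions strictly increasing within 20 chromosomes.  The
block-copy scheme is an invented stand-in for the CC founder mosaic; it
preserves the marker multiplicity that makes per-SNP testing and BH
correction behave realistically.

**Planted causal chain.** Three loci on distinct chromosomes carry one
shared, balanced strain distribution pattern (SDP) `T`.  SDP multiplicity
across unlinked loci is characteristic of small multiparental panels, and
with only 30 strains against thousands of independent null patterns no set
of three *independent* causal patterns can rank reliably ahead of the best
chance-aligned null pattern in a marker-wise scan; a shared planted SDP is
the design under which single-marker selection has a well-defined target.
Each locus is paired with a mediator family (Ruminococcaceae up in
high-anxiety mice, Bacteroidaceae and Clostridiaceae down, matching the
directions the assay literature reports):

* mediator: per cage `c`, family `j`: `M_cj = alpha0 + alpha1_j T + sigma z_cj`
  with `alpha1 = 1.0` (natural-log fold change of family abundance) and
  cage noise `sigma = 0.7`;
* outcome: per mouse, `P(HA) = Phi(beta0 + beta1 T + sum_j beta2_j M_cj)`
  with `beta1 = 0.3`, `|beta2| = 0.45`, and `beta0` centering the class
  balance.  About 60% of the planted allele's probit-scale effect is
  mediated (`3 * alpha1*beta2` of `beta1 + 3 * alpha1*beta2`).

These magnitudes were chosen so that (i) anxiety labels remain stochastic
within strains (intra-strain correlation ~0.4, so probit fits never
separate), (ii) the planted SDP's mouse-level chi-square (~110-155 at
n~450) clears the null-pattern extreme tail (~55-70), and (iii) planted
family shifts are detectable through the compositional closure without
dominating it.  The closed-form population ACME implied by the planted
parameters is recorded per pair
(`E[Phi(mu + s Z)] = Phi(mu / sqrt(1 + s^2))`, other planted mediators
following the treatment arm).

**Abundance.** OTU log-abundances are Normal around family-level bases;
planted families sit at a typical base share (so their fold-changes do not
dominate the compositional denominator) and receive a guaranteed OTU
contingent; non-planted families get cage-level log noise (SD 0.3).
Profiles are exponentiated and closed to sum 1 per cage, and every mouse
inherits its cage's profile exactly, reproducing the cage-shared design.
Closure makes null families co-vary (mostly opposite to the dominant
planted shift), so a handful of null families reach the family-level
FDR < 0.1 screen — a deliberate, realistic feature of relative-abundance
data under cage pseudo-replication, not a defect.  These extra families do
not survive the downstream allele screen.

**Behavior plans.** Each mouse's transition plan is drawn from its label's
regime: high-anxiety mice make fewer full transitions (1 + Pois(2) vs
4 + Pois(6)), fewer partial pokes (Pois(8) vs Pois(20)), spend less time in
the light (55 +/- 15 s vs 130 +/- 25 s), leave the light sooner
(10 +/- 4 s vs 30 +/- 10 s) and explore more slowly (45 vs 80 mm/s).
Magnitudes are free parameters set for clear (but not degenerate)
separation; noise-free profiles reproduce the planted counts exactly by
construction, which the round-trip tests exploit.

What the generator does **not** emulate: founder haplotype mosaics,
16S read-level noise, sequencing depth variation, non-Gaussian abundance
dispersion, behavioral drift within the assay.  Passing tests therefore
validate the inference machinery, not robustness to those real-data
features.

## Anxiety classification

Phenotypes are z-scored (raw Euclidean distance would be dominated by the
mm-scale distance phenotype), then Monti-style consensus clustering runs
k-means (10 restarts, tolerance 1e-6) on 100 subsamples of 80% of mice
drawn without replacement, reusing the same subsamples across K = 2..k_max.
Consensus entries are exact co-clustering frequencies
(times co-clustered / times co-sampled).  Stability is summarized by the
area under the empirical CDF of consensus values and the relative
delta-area curve; the final partition per K comes from average-linkage
hierarchical clustering of (1 - consensus), a common label-extraction
rule.  K is taken from configuration (default report covers K <= 4): on
synthetic cohorts, as in the assay literature, delta-area can favor K > 2
while the K = 2 matrix is the clean block structure.  The K = 2 cluster
with lower mean time-in-light is labeled HA (light avoidance is the
anxiety readout), with a deterministic tie-break on full-transition count.

Group differences use two-sided Mann-Whitney tests (exact enumeration when
both groups have <= 10 mice and no cross-group ties, otherwise the
tie-corrected normal approximation) with BH adjustment across the seven
phenotypes.  A joint logistic regression of label on all seven z-scored
phenotypes is attempted; on cleanly separated synthetic cohorts it is
usually perfectly separated, and the pipeline reports that condition
rather than coefficients — expected behavior, since the labels were
derived from the same phenotypes.

## Genetic association

Mice inherit their strain's allele.  SNPs keep only A/B strain calls
(heterozygous and missing calls count toward neither allele and their mice
are excluded per SNP); the MAF filter keeps SNPs whose minor allele is
carried by >= 3 of the 30 strains.  Each SNP is tested with the Pearson
chi-square on the mouse-level 2x2 allele x group table, *without*
continuity correction: at the p scales involved the correction is
immaterial and the uncorrected statistic has the clean closed form
`n (ad-bc)^2 / (r1 r2 c1 c2)` used as a test oracle.  Tables with a zero
margin report p = 1 with a flag.

Significant SNPs (strict `p < alpha`) map to every gene whose 1-based
inclusive interval contains them (BED input is converted from 0-based
half-open on load).  Overlap between mouse candidate genes and human GWAS
gene lists is an exact hypergeometric tail with case-insensitive symbol
matching; the default universe is the size of the supplied annotation.

**Threshold calibration.** The selection default is `alpha = 1e-13`.
Marker-wise mouse-level chi-square in a 30-strain panel is strongly
inflated for null markers by the strain-clustered labels (a null SDP that
happens to align with the strain-level anxiety profile carries a large
statistic), which is precisely why such designs need extreme thresholds.
For the synthetic study conditions the calibrated value is `alpha = 1e-20`
(chi-square ~87): planted-SDP markers sit at 110-155 while the null
extreme tail stays below ~70 across seeds.  The threshold is configuration,
never hard-coded.

## Microbiome association

Family abundances are sums of member-OTU relative abundances (mass is
conserved exactly).  Differential abundance uses the same Mann-Whitney/BH
machinery at FDR < 0.1 (family) and FDR < 0.05 (OTU).  Flagged taxa get
univariate logistic odds ratios per SD of abundance (z-scored relative
abundance; no rarefaction or CLR, matching the upstream convention) with
Wald CIs and BH adjustment.  Prediction uses a random forest (1000 trees)
over 100 stratified 90/10 train/test iterations; accuracy is averaged per
iteration while the ROC/AUC pools all held-out class probabilities
(pooled ROC is deterministic given seeds and simple to specify exactly).
Splits are stratified to prevent empty-class test sets; impurity-based
importances are averaged and reported ranked.  Cage pseudo-replication is
inherited from the design deliberately; cage-level collapsing is available
as a sensitivity flag.

## Mediation

For each candidate (SNP, taxon) pair — SNPs already anxiety-significant,
pairs passing the allele-abundance Mann-Whitney screen at p < 1e-9 — the
models are `M = alpha0 + alpha1 T + eps` (least squares) and
`P(Y=1) = Phi(beta0 + beta1 T + beta2 M)` (probit MLE; a step-halving
Fisher-scoring Newton solver, validated against statsmodels, fast enough
to refit inside every bootstrap draw; coefficients beyond |15| on
standardized inputs are treated as separation).  Effects compose on the
probability scale with counterfactual mediator values drawn from the
fitted Normal mediator model: ACME contrasts M(1) vs M(0) at fixed
treatment, ADE contrasts treatment arms at fixed mediator, both averaged
over the two arms.  The mediator model has no covariates beyond T, so the
per-unit draws pool into a single Monte-Carlo sample (200 draws per unit
for point estimates, 2000 pooled draws with common random numbers inside
the bootstrap); sharing draws across the four treatment/mediator
combinations makes `total = ACME + ADE` exact.

Inference is a nonparametric bootstrap over mice (1000 refits; cage-level
resampling available), with percentile CIs and the two-sided sign-test
p-value floored at `1/(n_boot+1)`.  Non-converged bootstrap draws are
discarded and counted; beyond 10% the pair is flagged unreliable and
carries no evidence (p -> 1).  BH runs across all tested pairs; SNPs in
perfect linkage (identical strain pattern) are fitted once and broadcast,
which changes no statistic.  Significant SNPs collapse into loci within a
1 Mb window.

Because the analyst's mediator is the z-scored *relative* abundance — an
exponential, closure-coupled transform of the latent log-scale mediator —
estimated ACMEs are attenuated relative to the planted latent values
(roughly 0.06-0.12 vs 0.137 at the defaults); signs and significance are
preserved, which is what the recovery criteria assert.

## Problem sizes and numerical choices

The shipped analyses and tests run at the full simulated design
(~450-500 mice, 134,593 SNPs, 5,761 OTUs); unit tests use a reduced cohort
(4,000 SNPs, 400 OTUs) where the full scale adds nothing.  Calibration
experiments use 200 replicate cohorts at n = 400 with 400 bootstrap draws
(the package default stays 1000), and the n = 5000 point-estimate check
averages five cohorts because a single cohort carries ~0.011 sampling SE
on the ACME.  Degenerate inputs fail loudly: NaN area fractions name the
offending frame, constant phenotype or abundance columns are rejected,
zero-margin tables and zero total effects are flagged rather than divided
through.

## Known limitations

* Marker-wise chi-square cannot distinguish a causal SDP from a perfectly
  correlated tag SDP; discoveries are therefore assessed at the
  (strain pattern, taxon) level.
* Sequential ignorability is assumed, not probed; no multi-mediator joint
  model.
* The family-level screen inherits cage pseudo-replication and is
  anti-conservative for cage-structured null taxa; the allele screen
  downstream absorbs this in the mediation chain, but family flags alone
  should be read accordingly.
* The probit outcome model per pair omits the other planted mediators;
  estimates are attenuated accordingly (omitted-variable noise), which the
  recovery-based criteria tolerate by design.
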