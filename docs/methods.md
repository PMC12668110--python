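# Methods

`pgsepi` detects statistical epistasis between individual SNPs and the
aggregate additive background of a quantitative trait, represented by a
polygenic score (PGS). This note documents the models, the defaults and the
numerical choices, and what the synthetic-data studies do and do not show.

## The interaction model

For each variant the package fits, by ordinary least squares,

    y_i = α + β·g_i + γ·PGS_i + δ·g_i·PGS_i + ε_i            (whole-score model)

where `g_i` is the minor-allele dosage and the coefficient of interest is
the interaction δ. Testing a SNP against the *sum* of many small effects
rather than against single partners concentrates what would be many tiny
pairwise interaction effects into one coefficient, which is what makes the
test powered at biobank-like sample sizes.

Two safeguards address the known failure modes of interaction scans:

1. **Phantom epistasis / LD leakage.** The score used for a focal SNP is the
   leave-one-chromosome-out (LOCO) version: no variant on the focal SNP's
   chromosome contributes, so LD between the SNP and score members cannot
   manufacture δ. The decomposition `score_full = loco[k] + partial_k` is
   exact to machine precision.
2. **Global (non-specific) epistasis.** A smooth non-linearity between the
   summed genetic effects and the trait induces interactions between *all*
   variant pairs; these are treated as false positives. Before scanning,
   each score is replaced by the interpolated bin-mean phenotype ("mean
   correction"): individuals are sorted by score and binned (20 bins of 50
   at each tail, interior bins of 1000; for n below the full scheme all
   three knob values are scaled proportionally, with the last interior bin
   absorbing remainders), knots are the per-bin score median and phenotype
   mean, and scores are mapped through the piecewise-linear interpolant.
   Beyond the terminal knots the terminal segment's slope is continued;
   flat clipping would itself create tail interactions.

The dependent variable is the covariate-residualised, rank-inverse-normal
transformed (INT) phenotype from which the full (non-LOCO, mean-corrected)
score and, when supplied, its products with structure covariates are also
regressed out. INT uses average ranks and the offset (r − 0.5)/n.

Genome-wide significant interactions (default p ≤ 5e-8) are distilled into
independent hits by forward stepwise selection in decreasing significance;
each candidate contributes its dosage, its squared dosage and its
score product, and is retained only if its interaction term stays
significant in the joint model. The squared term prevents single-locus
dominance or recessiveness from masquerading as interaction. Perfectly
collinear candidates (e.g. duplicate variants) are dropped by a rank check.

## PGS construction

The scan score is built by clumping and thresholding with a deliberately
loose LD cutoff (r² ≤ 0.90 within 1 Mb, greedy by increasing p, ties broken
by chromosome and position) and a p-value threshold selected by held-out
predictive r² on a seeded 90/10 split over the candidate grid
{5e-8, 1e-6, 1e-5, 1e-4, 1e-3}. Greedy retention depends only on
more-significant variants, so the retained set at a stricter threshold is a
subset of the looser one; the implementation clumps once at the loosest
candidate and subsets.

Loose clumping double-counts correlated neighbours, so marginal weights are
corrected toward the joint multiple-regression fit by cyclic coordinate
descent on the centered design (tolerance 1e-6 on the largest weight
update, 100 sweeps, updates computed on a precomputed Gram matrix). When LD
makes cyclic descent slow (neighbours at r² near 0.9 give Gram condition
numbers in the hundreds), the adjustment is completed at the same limit
point by a direct minimum-norm solve of the normal equations. The
postcondition — a residual GWAS of `y − score` on the score's variants has
no genome-wide significant hit — therefore holds by construction and is
asserted in the test suite.

## Pairwise refinement

Each independent hit is tested against every other variant with
`y ~ 1 + g_focal + g_partner + g_focal·g_partner` on the residual+INT
phenotype *without* score adjustment. Partners within 1 Mb of the focal SNP
are cis-flagged and excluded (local LD is where phantom epistasis lives).
Surviving pairs are tiered: *main* requires both MAFs ≥ 1%; *secondary*
requires interaction frequency — mean(g₁·g₂)/2, the pair analogue of allele
frequency — of at least 0.1%; the /2 divisor follows the printed
definition (with a homozygous partner it returns twice the other SNP's
MAF, not the MAF itself; the constant is configurable in spirit but kept
verbatim). Interacting networks of 2–10 SNPs are refitted jointly with
main, squared and all pairwise product terms, effect alleles flipped so
main effects are non-negative; edges are classed strong (p ≤ 5e-8) or
suggestive (p ≤ 1e-4).

## TF-partitioned scores

A separate, sparser score (standard C+T, clump r² ≤ 0.10) seeds the
partitioning. Each hit ("driver") is extended to its tags (r² ≥ 0.75 within
1 Mb); exactly one causal variant per region is assumed. Per-tag evidence
is a Wakefield approximate Bayes factor from the marginal estimate and SE
with prior effect variance W = 0.04 (only relative, within-region values
matter after normalisation; computed in log space).

Annotations enter through a prior on which tag is causal,
Pr(t causal) ∝ 1 + a_t(α − 1), with the enrichment α estimated by maximum
likelihood of the per-region mixture Σ_t π_t(α)·BF_t, optimised on log α in
[log 0.01, log 100] (bounded scalar optimisation, xatol 1e-6). Annotations
constant within every region leave α unidentifiable (flagged, α = 1);
estimates at the box edge are flagged `boundary`; the returned likelihood
is never below the α = 1 null. For histone marks with many candidate peak
datasets, the model is fitted per dataset and the highest-likelihood
dataset is kept. Histone α values are estimated once in the annotation-only
stage and held fixed when each motif's α is fitted (staged, not joint,
estimation).

Motif evidence is quantitative: the best log-odds match of the motif's
position count matrix (pseudocount 1 per cell, uniform background) over
both strands, both alleles and every placement overlapping the SNP inside a
60 bp window. The raw score is converted to an odds ratio against sequence
context: the ratio of add-one-smoothed empirical survival probabilities of
the score under an enhancer background (random SNPs in H3K4me1 peaks)
versus a non-regulatory background (SNPs in neither H3K4me1 nor H3K4me3),
made monotone by isotonic regression and floored at 1. Windows shorter than
the motif score −inf and force OR = 1.

Per-tag weights combine the evidence as

    w = [1 + (OR − 1)(α_m − 1) + a_c(α_c − 1)] · [1 + a_h1(α_h1 − 1)] · [1 + a_h3(α_h3 − 1)]

with the TF and coding routes additive inside the first factor (they are
biologically alternative mechanisms) and histone factors multiplicative;
each factor is floored at 0 since weights model prior probabilities.
Products BF·w are deliberately *not* renormalised within regions — the
weights up- or down-weight the score rather than re-divide it. The TF score
is TFS_i = Σ_d Σ_t BF·w·β_d·g_it with LOCO versions, and enters the
six-term model

    y = α + β·g + γ·PGS + δ·g·PGS + ζ·TFS + η·g·TFS + ε

so that η is only significant when the TF component behaves differently
from the score as a whole (threshold 1e-5, a Bonferroni allowance for up to
~1000 TF scores per trait). TF scores nearly collinear with the PGS
(r² > 0.999) are skipped. Finally, any signal explained by a single
pairwise partner is removed: significant pairwise partners of the focal SNP
and their own tags (r² ≥ 0.80) are excluded from the TF score and the test
rerun; signals that vanish are flagged pairwise-driven.

## Synthetic data

The generator produces individuals × variants dosage matrices over 22
labelled chromosomes. Haplotypes follow a latent-Gaussian block model:
within an LD block (geometric lengths, default mean 20 variants) latent
values are equicorrelated with ρ (default 0.8) and thresholded at each
variant's allele-frequency quantile; dosage is the sum of two haplotypes,
oriented to the minor allele. Variants in one block share a haplotype
history, so their target frequencies are drawn as one per-block base MAF
(uniform over the MAF bounds by default; a log-uniform spectrum is
available) with multiplicative log-normal jitter (σ = 0.15) — without
frequency matching, thresholded indicators cannot reach realistic
within-block r². Positions are random walks with mean spacing 30 kb.
Blocks are independent, so there is no inter-block or inter-chromosome LD,
no recombination-map realism and no attempt to mimic any particular
cohort's LD; missing genotypes are not generated (QC paths are tested with
injected missingness).

Null traits cover a 72-cell architecture grid: causal count
{100, 1000, 10000} × positioning {random, clustered} × effect-size
frequency adjustment {none, ldak} × global transform
{none, sigmoid before noise, sigmoid after noise} × heritability
{0.30, 0.60}. Clustered placement puts half the causal SNPs into 1 Mb
regions with truncated-Poisson(5) occupancy. The ldak adjustment multiplies
effects by [2p(1−p)]^−0.25. The "scaled sigmoid" is a logistic on the
standardized scale (steepness 1) affinely rescaled to preserve the input's
mean and variance, which keeps heritability bookkeeping interpretable.
Noise is orthogonalised against the genetic component in-sample and scaled
so realized additive heritability is exact.

Interaction traits start from the 1000-causal random architecture. 22 focal
LHS SNPs (MAF ≥ 5%) split 8/8/6: eight causal ("direct"), eight non-causal,
six non-causal "biased" whose targets are drawn 4:1 from positive-effect
causal SNPs (their interaction term correlates with their own dosage, so
they acquire a positive estimated direct effect without any injected main
effect). RHS target-set sizes cycle round-robin over {1, 20, 100, 1000}
within category; biased SNPs cycle over {1, 20, 100} because the full
causal set cannot satisfy the 4:1 proportion. One sign per LHS applies to
all its targets. Eight traits share the architecture, crossing frequency
adjustment {none, ldak} with interaction magnitude c ∈ {0.01, 0.1, 0.5, 1};
the interaction term is sign·c·β_j·g_l·g_j with β on the scale where the
additive component has unit variance, so a positive sign scales up every
target's effect in absolute value. Additive heritability of these traits is
fixed at 0.30.

## Evaluation studies and their scales

- **Null calibration** (`run_null_calibration`): 10 datasets at n = 2,000,
  m = 5,000 spanning the grid (10,000-causal cells capped at m/2), each run
  through the full pipeline; reports the pooled KS uniformity p of the
  interaction p-values and per-run genome-wide hit counts. The scan is
  mildly conservative for strong sparse traits (p-values shifted toward 1),
  a consequence of scanning a dependent variable that already had the full
  score regressed out; the pooled KS bound still holds at these scales.
- **Interaction recovery** (`run_interaction_recovery`): 20 panels at
  n = 20,000, m = 1,500. Each analysed trait gets its own estimated score
  (C+T threshold fixed at 1e-4 here so score composition is comparable
  across the eight sibling traits; held-out selection is exercised in the
  calibration study). Coefficient recovery is checked on the standardized
  raw trait: the rank-INT used for discovery deliberately gaussianises the
  tails where interaction variance lives, so no "true coefficient" exists
  on the INT scale. The prediction for each focal SNP projects the *total*
  true interaction component — first adjusted for the full-score
  projection exactly as the pipeline adjusts the phenotype — onto the
  fitted design; the fitted δ must land within 3 SE. Power is reported by
  magnitude and by RHS-set size from the three all-trait runs.
- **Linearisation check** (`sigmoid_linearisation_check`): an off-centre
  sigmoid mean at n = 50,000; the quadratic coefficient's |t| falls from
  far above 10 to below 3 after mean correction.

Passing these studies shows the machinery is correctly calibrated and
powered *under the block-LD generative model*; it does not establish
performance under real LD (long-range structure, frequency–LD coupling),
under population stratification, or for case/control traits, which are out
of scope.

## Numerical and API notes

- All per-variant scans solve stacked 4×4 normal equations in batch;
  degenerate columns (zero variance or scale-relative determinant
  underflow) are flagged and reported with p = 1. p-values use the t
  reference with n − k degrees of freedom throughout (the Normal
  approximation would be indistinguishable at n > 1000 but matters in
  toys); exact-fit p-values are floored at the smallest positive float so
  p ∈ (0, 1].
- Missing dosages are mean-imputed per variant (preserving MAF) before any
  regression; Hardy-Weinberg is tested by a 1-df chi-square on hard calls
  rounded from dosages, since HWE is undefined on fractional values.
- QC boundaries are inclusive: MAF ≥ 0.001, missingness ≤ 0.05,
  HWE p ≥ 1e-10, INFO ≥ 0.8.
- BED intervals are 0-based half-open; variant positions 1-based; a
  position overlaps [start, end) iff start + 1 ≤ pos ≤ end.
- Determinism: every stochastic routine takes a seed; identical inputs,
  config and seeds give bit-identical outputs, including result TSVs.
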