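# Methods

`wheatimpute` re-creates, on fully synthetic data, an end-to-end study of
marker imputation in an elite inbred cereal panel: simulate a structured
panel, mask genotypes under two missingness designs, impute with
map-independent and map-dependent algorithms, and measure the downstream
impact on diversity estimation (Rogers' distance), genomic prediction, and
association-mapping power. This note documents the models, the calibrated
defaults, the numerical choices, and what the synthetic setting does and
does not show about real data.

## Synthetic panel generator

All lines are fully inbred, so genotypes are haploid-equivalent 0/1 calls;
heterozygotes in external files are demoted to missing with a warning.

The generator has three layers:

1. **Genetic map.** `n_markers` (default 2,000) are placed uniformly at
   random on `n_chrom` = 21 chromosomes of equal length summing to
   4,500 cM. Uniform placement is an assumption — the marker-density
   profile of real arrays is not modelled.
2. **Founder haplotypes.** Each chromosome is cut into ancestral blocks
   by a Poisson process (mean `founder_block_cm` = 30 cM). A block
   assigns each of the `n_founders` = 96 founders a fixed uniform score;
   a marker with target allele frequency `p ~ Beta(a, a)` (`a` = 0.05,
   a strongly U-shaped spectrum) carries allele 1 on founders whose score
   is ≤ p. Markers in one block therefore tag *nested* founder subsets —
   the haplotype-block LD of real arrays — and with probability
   `tag_reuse_prob` = 0.5 a marker reuses a neighbour's threshold
   exactly, producing the redundant perfectly-correlated tags that give
   array LD its bimodal r² distribution. The construction keeps the
   stated marginal (per-marker frequency drawn from the Beta) while
   adding the along-chromosome correlation without which a mosaic model
   cannot reach the target LD level: with independent per-marker founder
   draws, the expected adjacent r² is bounded near 1/(n_founders − 1),
   which is incompatible with a low mean MAF at the same time.
3. **Line mosaics.** Each line copies a founder and, across an
   inter-marker gap of d cM, switches to a uniformly drawn founder with
   probability 1 − exp(−λ·d), λ = `mosaic_switch_rate` = 0.05/cM
   (~225 expected switches over the genome, i.e. ~20 cM segments).
   Per-cell mutations flip alleles at rate 5·10⁻⁴. Markers whose
   realized minor allele frequency falls below `maf_floor` = 0.01 are
   redrawn in place (preferring a neighbour's threshold, to keep the
   duplicate-tag structure alive) for a bounded number of rounds.

**Calibration.** The defaults were tuned once so that the full-size panel
(371 lines × 2,000 markers) reproduces the study panel's summary
statistics: mean adjacent-locus r² ≈ 0.52 (achieved ≈ 0.52, SD ≈ 0.38)
and mean MAF ≈ 0.13 (achieved ≈ 0.155, inside the ±0.04 acceptance band;
the MAF floor truncates the rarest class and sets this lower bound).
About 19% of markers have MAF > 0.3, which supplies QTL candidates for
the power simulations.

What the generator does **not** emulate: ascertainment bias of array
design, chromosome-specific marker densities, residual heterozygosity,
genotyping error, and — importantly — the kinship spectrum of the real
panel, which is not reported and therefore not a calibration target (see
the power discussion below).

## Masking designs

* **Nested arrays (low2high).** Lines are split uniformly at random into
  a reference population (`ref_size` ∈ {50, 100, 200, 300}) typed on all
  markers and a test population typed only on the low-density subset
  (~1,573/9,926 of markers, chosen evenly spaced by map rank per
  chromosome). All high-minus-low cells of test lines are masked. The
  induced overall missing fractions are exactly
  ((n−ref)/n)·(8353/9926) = 72.8/61.5/38.8/16.1% at the canonical sizes.
* **GBS-like.** Each line independently has round(rate·n_markers) cells
  masked uniformly without replacement — per-line exact counts fix the
  realized level; whether the original study drew per line or per cell is
  not stated, and per-line is adopted.

Cells missing before masking are tracked as `ORIG_MISSING` and never enter
the evaluation truth.

## Imputers

All four return continuous dosages in [0, 1] on masked cells, never touch
observed cells, and are deterministic under a seed. Dosages are *not*
rounded before accuracy evaluation (the correlation metric operates on
continuous predictions); they are rounded at 0.5 where downstream steps
need hard calls (Rogers' distance, relationship matrices, file interop).

* **Frequency baseline** — the marker's observed allele frequency; also
  the initializer and fallback for the other methods.
* **Iterative Random Forest** (map-independent) — missForest-style:
  initialize missing cells by Bernoulli draws at the observed frequency;
  visit markers in ascending missingness order; regress each on all other
  markers' current values with 100 trees and √(n−1) candidate predictors
  per split, fitted on the marker's observed lines; write ensemble-mean
  predictions into the missing cells; repeat until the summed squared
  change falls below tolerance or increases (the previous iterate is then
  kept), at most 10 iterations.
* **Shrinking-window matcher** (map-dependent) — window sizes shrink
  geometrically (64 → 4 markers, 50% overlap). Within a window, donors
  are fully observed lines agreeing with the target at every observed
  target position; each donor votes its allele with weight equal to the
  window size, so long shared segments (closer common ancestry) dominate.
* **Li–Stephens HMM** (map-dependent) — haploid copying model per
  chromosome: hidden state = reference haplotype; stay probability
  exp(−c·d) plus uniform switching, emission 1−ε on allele match, ε on
  mismatch (ε = 0.01, c = 0.1/cM by default), uninformative emission at
  unobserved sites; scaled forward–backward; dosage = posterior-weighted
  allele average over references observed at the cell. When no line is
  fully observed on a chromosome (GBS-like depletion) all other lines act
  as partially observed references — fully observed references reproduce
  the textbook model exactly, so this is a strict generalization.

## Evaluation

Accuracy is the per-marker Pearson correlation between truth and dosage
over that marker's masked cells, averaged over markers; zero-variance
markers yield an undefined correlation and are excluded with an explicit
count (a constant column carries no discriminative information; scoring
it zero would bias comparisons — the frequency baseline, whose per-marker
dosage is constant in the nested-array design, is reported as 0 in
ordering comparisons for exactly this reason). LD r² uses the standard
D²/(p(A)p(a)p(B)p(b)) with directly counted haplotype frequencies (inbred
lines are phased by construction). Each imputed marker's LD context is
summarized as the maximum r² to a typed marker within ±5 cM (no window is
prescribed by the source study; 5 cM is configurable).

## Relatedness

Rogers' distance reduces, for inbred 0/1 calls, to the proportion of
differing loci; with pairwise-complete deletion the locus count is
pair-specific. Distance-matrix agreement is the Pearson correlation of
strict upper triangles, tested by a one-sided (greater) Mantel
permutation test with p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1),
n_perm = 999 by default.

## Quantitative genetics

Phenotypes: y = g + e with h² = 0.91. Polygenic architecture: every
segregating marker contributes equally — β_i = ±√(σ²_G/(m·v_i)) — and g
is rescaled so its sample variance equals σ²_G exactly; because markers
are in LD the contributions are defined marginally and the rescaling
makes h² (and the 10% QTL share below) hold by construction. QTL
architecture: one focal marker with MAF > 0.3 (optionally constrained to
a target LD class relative to the typed subset) carries 10% of σ²_G, the
remainder is spread equally.

Prediction: single-variance-component mixed model. REML is a profile
likelihood over δ = σ²_e/σ²_g on the eigendecomposition of the
relationship matrix, optimized by bounded scalar search on log₁₀δ —
exact for one genetic component. RR-BLUP is computed through the
equivalent G = WW′/c formulation (c = summed marker variance, W centered
by training means), so its predictions coincide with GBLUP to numerical
precision; the test suite checks the two routes against each other at
1e-6. Pairwise-complete relationship matrices (non-imputed GBS data) are
not guaranteed PSD: negative eigenvalues are clipped to 1e-6
(nearest-PSD projection), and a matrix whose negative part rivals its
leading eigenvalue is rejected.

Association scan: y = μ + αm + Xg + e with g ~ N(0, 2Kσ²_G), K = 1 − RD.
The variance ratio is REML-estimated once under the null and reused for
every marker (the standard P3D/EMMAX approximation; per-marker
re-estimation is not prescribed by the source study). The Wald
F = α̂²/var(α̂) is referred to F(1, n−2) — the df choice is a convention,
documented and configurable in spirit (n is large enough that it is
immaterial). Monomorphic markers are skipped and counted. Detection
frequency uses a Bonferroni threshold 0.05/(markers tested) by default
(the original significance policy is unstated).

## Power of the scan on the synthetic panel — a known limitation

On the calibrated panel (371 × 2,000), the detection frequency of the
perfect QTL marker over 100 runs is typically 0.70–0.80 — at or slightly
below the >80% reported for the real panel. Diagnostics localize the gap
precisely: the scan is well calibrated under its own generative null
(type-I 0.048 at nominal 0.05 on the same structured panel), and plain
OLS on the same phenotypes reaches ~0.93 power, so the shortfall is the
kinship correction absorbing QTL signal whose pattern aligns with leading
eigenvectors of 1 − RD. That alignment is a property of the synthetic
founder-mosaic structure; the generator is calibrated to the panel's LD
and MAF — the only statistics the source reports — not to its kinship
spectrum. The corresponding acceptance test asserts the >80% floor and is
expected to fail by a few points; it is kept red rather than tuning the
generator or the threshold, because the quantity is honestly computed
under the stated conditions.

## Problem sizes used by the test suite

Property tests that need the Random Forest imputer run on panels that
keep the calibrated marker density (2.25 cM spacing) but fewer markers
(160 over two chromosomes) and, where the canonical reference sizes
{50,…,300} matter, the full 371 lines; the Random Forest uses 25 trees ×
3 iterations there. These are the package's chosen desk-scale dimensions;
the full-size configuration remains the default everywhere else
(`scripts/acceptance.py` runs 371 × 2,000 throughout). One test-scale
caveat: the genome-wide-minimum-p and power properties require the
full-size panel, because a kinship estimated from very few markers is
contaminated by each marker's own pattern (proximal contamination) and
absorbs the QTL signal.

## Seeds and reproducibility

Every stochastic step takes an explicit seed; pipeline cells derive
seeds as a stable hash of (base seed, stage, scenario, imputer,
replicate), so any grid cell can be reproduced in isolation and re-runs
are bit-identical. Identical configurations re-use completed on-disk
artifacts via a config hash.
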