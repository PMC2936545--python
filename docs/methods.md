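# Methods

This note records the statistical models implemented in `llnet`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that a maintainer or
reviewer would want spelled out.

## Preprocessing

**Technical replicates.** Bead-array samples arrive as two replicate
arrays with per-probe bead counts. All replicate columns are
log2-transformed and quantile-normalized together, then each sample's
replicates are correlated; a sample is dropped when Pearson Ρ < 0.94 or
Spearman ρ < 0.60. Kept pairs are combined probe-by-probe as the
bead-weighted mean `δ_p = (b1·S1 + b2·S2) / (b1 + b2)`. The weighting is a
normalized mean rather than a raw weighted sum: an unnormalized sum would
scale intensities with total bead count, and the normalization constant
cancels in every downstream correlation or regression statistic. MA
coordinates (M = log2 ratio, A = mean log2 intensity) are computed per pair
for inspection; no automated curvature test is applied.

**Quantile normalization** forces every column to the cross-column mean
quantile vector; ties within a column receive the mean of the quantile
values they span. The operation is idempotent to machine precision. A
`groups` argument allows per-strip normalization when strip metadata
exists; the generator produces no strip structure, so the default is
dataset-level.

**Probe filters.** Keep = autosomal ∧ not a globin probe ∧ unique genomic
mapping. Annotations carry these three fields explicitly.

**Trait standardization.** Lipid traits are processed separately within
each sex: an Anderson–Darling normality test (case with estimated mean and
variance, Stephens small-sample correction; P value from the standard
piecewise-exponential approximation, verified against R `nortest`) gates a
Box–Cox transform whose λ is estimated by profile maximum likelihood; the
(possibly transformed) values are standardized to Z-scores and the sexes
recombined. Per-sex λ is used throughout, consistent with treating the two
sex distributions separately. Non-positive values in a trait that needs
transforming raise an error instructing the caller to shift or exclude
them rather than silently shifting.

**Genotype QC.** A sample is dropped when its call rate is below 0.95;
a SNP is kept iff call rate > 0.95, minor-allele frequency > 0.01, and the
Hardy–Weinberg *exact* test P > 10⁻⁶. The exact test conditions on allele
counts and sums the probabilities of all heterozygote configurations no
more likely than the observed one; it is verified against a full
enumeration oracle in the tests. External sample exclusions (fingerprint
concordance, relatedness) are accepted as a list, not recomputed.

**Population-structure outliers.** Each SNP's dosage is residualized on
the two preceding SNPs of its chromosome (position order) to damp local
LD, standardized, and the sample covariance spectrum is computed by SVD.
Components are declared significant while their Tracy–Widom P < 0.01,
using the moment-matched effective marker count at each successive
eigenvalue; a sample is an outlier if it lies more than 8 standard
deviations out along any significant component. One pass is made, no
iterative re-run after removal. The TW1 tail is evaluated with the
shifted-gamma approximation of Chiani (2014), accurate to about 10⁻⁴ in
CDF — far finer than the 0.01 gate; the 95th/99th percentiles reproduce the
literature values (0.9793, 2.0234) in the tests.

## Association

Univariate: OLS of a trait Z-score on one probe's expression plus that
trait's covariates (age, cholesterol/hypertension medication as binary
factors, alcohol in grams where applicable), implemented through the
Frisch–Waugh projection so thousands of probes share one covariate
residualization. Significance is gated at nominal P < 0.05/m with the
corrected P reported as min(1, mP). Sex enters through the prior per-sex
standardization, not as a covariate. Covariates that do not increase the
design rank are dropped with a warning.

Cell-type covariates are the per-sample mean of Z-scored marker probes for
each cell type; in a simulation where a latent cell-fraction drives both
expression and trait, adding them restores the nominal 5% type-I error.

Multivariate ("meta-lipid"): all seven trait Z-scores form Y; the tested
regressor's Wilks' Λ = det(E)/det(E+H) is converted to P with Rao's F
approximation (exact when min(k, q) ≤ 2). The same core serves the
module-level eQTL test with Y = module expression and X = dosage.
Agreement with `statsmodels` MANOVA is asserted to 10⁻⁸ in the tests;
under the null the P values are uniform by KS test.

Spearman statistics everywhere use midranks and the t approximation
`t = ρ√((n−2)/(1−ρ²))` on n−2 degrees of freedom, two-sided.

## Network

Adjacency is unsigned, `|cor|^β`, since trait correlations of both signs
occur inside one module. β is the smallest power on the grid 1..20 whose
signed scale-free fit exceeds 0.80 — the smallest qualifying power also
maximizes mean connectivity among qualifying powers, matching the stated
twin criteria. The scale-free fit bins positive connectivities into ten
equal-width bins and regresses log10 frequency on log10 mean connectivity;
the R² is signed by the negative slope sign so that decaying distributions
score positively.

Module detection clusters 1 − TOM (unsigned topological overlap; plain
1 − adjacency available by option) under average linkage and cuts the tree
at a constant height placed 90% of the way from the lowest merge height to
the median merge height, then enforces a minimum module size of 10.
Rationale: tight planted branches merge far below the dendrogram bulk
(whose merges concentrate near the median), so this cut isolates them; on
uncorrelated data minimum and median nearly coincide and average linkage
pulls any growing cluster's merge height back to the bulk, so no spurious
module reaches the minimum size. The 90% placement was calibrated once on
the generator's default conditions (perfect or near-perfect recovery
across seeds, zero spurious modules on shuffled data) and is exposed as a
parameter. This is a deliberately simple constant-height variant of
dynamic branch cutting; the hybrid PAM variant is out of scope.

Eigengenes are the first right-singular vector of the probe-standardized
module submatrix, scaled to unit variance and oriented so the mean
correlation with member probes is positive. Modules whose eigengene
dissimilarity (1 − cor) merges below 0.20 under average linkage are
merged and eigengenes recomputed, iterating to a fixed point.

Module–trait association uses the Spearman t-test per (eigengene, trait)
at an alpha divided by the extrapolated module count
(modules × total probes / subset probes); the worked arithmetic
(23 × 35419 / 1000 = 814.637 → 6.14×10⁻⁵) is pinned in the tests. Module
membership kME = cor(probe, eigengene) and gene significance
GS = |cor(probe, trait)| are reported per probe with their within-module
correlation.

## eQTL

cis: per-SNP simple OLS with pairwise deletion of missing dosages,
minimum 10 complete pairs, monomorphic SNPs skipped with a reason.
Permutation calibration permutes expression against genotypes and records
the minimum nominal P across the probe's cis SNPs per permutation (the
min-P convention); the empirical P uses the +1 correction and is gated at
0.05. Missing dosages are mean-imputed inside the permutation scan so all
cis SNPs share one sample set; with 10,000 permutations the resolution is
10⁻⁴. trans: Spearman with dosage midranks at a fixed 5×10⁻⁷ threshold —
the analytic shortcut is used because re-permuting genome-wide per probe
is out of proportion to the gain. Windows: cis ≤ 1 Mb from the probe
midpoint, trans > 5 Mb or another chromosome, the band between excluded
from both. Positions are 1-based; allele relabelling flips slopes but not
P values (asserted as a property).

## SEM and edge orientation

Path models are parameterized in RAM form (path matrix, diagonal residual
variances plus explicit free residual covariances, filter to observed
variables); the ML discrepancy `log det Σ + tr(SΣ⁻¹) − log det S − p` is
minimized with L-BFGS-B from regression-based start values (convergence
tolerance 10⁻¹⁰ on the discrepancy; variances floored at 10⁻⁶). Model
chi-square is (n−1)·F_min with df = moments − parameters; standard errors
come from the inverse numerical Hessian of the log-likelihood; variables
are standardized before fitting so paths are on the correlation scale.
Model-fit P values are verified uniform under their own generating models.

The five competing models for an edge A–B with orthogonal anchors
(anchor–anchor covariance fixed at zero, as "orthogonal" implies):

1. causal `M_A→A→B←M_B`
2. reactive `M_A→A←B←M_B`
3. confounded: anchors on A and B plus a free residual covariance between
   A and B — the identified equivalent of a unit-variance latent confounder
   with free loadings (the free-loadings parameterization is a ridge in
   which only the loading product is identified, which silently deflates
   its fit P; the correlated-residual form has the same implied covariance
   set and a proper df of 3)
4. pleiotropy `M_A→B` added to the anchor-only model (no A–B edge)
5. pleiotropy `M_B→A` likewise.

`LEO.NB.OCA = log10(P_causal / max competing P)`. A directed edge is
declared when |Pearson(A,B)| > 0.3, LEO ≥ 0.3 and |path Z| > 1.96;
orientations whose causal model itself fits at P ≤ 0.05 carry a caveat
flag, and anchors correlating with their node below 0.3 are flagged weak.
Anchor auto-selection offers the greedy best-P SNP and forward-stepwise
regression (partial-F entry at 0.05), with a cross-assignment check that a
selected SNP associates most strongly with its own node.

**Operating-point dependence of the false-positive rate.** The 0.3
threshold's advertised false-positive rate (< 5%) is not an intrinsic
property of the score: it depends on how strongly the confounded
alternative deviates from the causal model. With anchors explaining 10% of
node variance and n = 500, the causal model's misfit noncentrality under a
latent confounder with paths c each is roughly n·r²_anchor·c⁴. At c = 0.7
(node correlation 0.49) the acceptance-style measurement yields ≈ 1% false
positives; at c = 0.6, ≈ 7%; at c = 0.5 (node correlation 0.25 — below the
0.3 edge threshold, so such pairs would not even qualify as edges in the
full procedure) the score-only false-positive rate is ≈ 10–12%, because
the causal model's fit P is then mediocre rather than small while the true
model's fit P is uniform. The bundled acceptance measurement uses c = 0.5
and reports the honest value.

## Synthetic-data generator

The generator emulates: five co-expression modules as single-factor models
(probe loadings uniform on [0.6, 1], unit factor and noise SD → pairwise
correlations ≈ 0.26–0.5, the "tightly co-expressed" regime), probe
baselines uniform on [6, 12] log2 units, 870 independent background probes,
technical replicates (log2 noise SD 0.15, bead counts uniform integer
10–60, 5% of samples with one replicate's noise inflated ×10 to trip the
0.94/0.60 gates), 10% of background probes flagged
non-autosomal/globin/multimapping, lipid traits with the published
sex-specific means and SDs, medication prevalences 20.5% (HTM) and 14.3%
(CM), Hardy–Weinberg genotypes on a 2-chromosome × 100 Mb layout with cis
eQTLs placed within 100 kb of their target probe (per-allele shift 0.8
noise-SD), and SNP anchors (R² = 0.1) imposing a chosen causal topology —
by default the anchored trait (TG) drives the first module's factor with
standardized path 0.5, with HDL (+0.3) and APOB (−0.3) loading on the same
factor. Defaults: 500 samples, 1000 probes, module sizes 40/30/25/20/15,
200 SNPs.

Not emulated: linkage disequilibrium beyond independent HWE draws,
background co-expression structure (background probes are independent),
array strips, batch effects, non-Gaussian trait shapes (raw traits are
Gaussian on the raw scale; the Box–Cox branch is exercised on separately
generated lognormal samples), and genotype imputation. Passing recovery
tests therefore demonstrate correctness of the algorithms under the
factor-model idealization, not robustness to the full messiness of real
cohort data.

All draws derive from per-stage `numpy` generator streams seeded from the
single configuration seed, so every artifact is bit-reproducible.

## Problem sizes used in the shipped checks

The acceptance-style checks run module recovery on the default 1000-probe
panel across several seeds, orientation across 20 generator seeds,
permutation calibration with 199 permutations × 1000 replicates, Wilks
null calibration at 1000 replicates, and the confounded-quartet
false-positive measurement at 500 quartets of 500 samples — sizes chosen
to make the whole suite run in minutes on one core while keeping every
statistical assertion comfortably powered.

## Known limitations

- The constant-height tree cut is a simplification of dynamic branch
  cutting; deeply nested or strongly unbalanced module structure would
  favor the adaptive algorithm.
- The permutation scan mean-imputes missing dosages; with informative
  missingness the empirical P could be slightly miscalibrated.
- Rao's F is approximate for min(k, q) > 2 (exact otherwise); at the
  sample sizes used here the approximation error is negligible.
- The SEM engine handles recursive path models over a handful of observed
  variables with at most simple latent structure — it is a purpose-built
  edge-orienting tool, not a general SEM package.
- VCF support covers the GT-only subset the paired writer emits (plus
  phased separators, missing calls, multi-allelic skipping), with strict
  line-numbered errors; it is not a general-purpose VCF parser.
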