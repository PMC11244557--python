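# Methods

## Imaging pipeline

### Preprocessing

Input volumes are assumed despiked, motion-corrected and registered;
the package starts from conditioned 4D series. The chain is
trim → nuisance regression → spatial smoothing → band-pass, in that
order, and each stage touches in-mask voxels only and is linear in the
data:

* **Trimming** removes the initial equilibration frames (default 50) and
  contracts any paired nuisance set to match.
* **Nuisance regression** residualizes every voxel on an intercept, six
  rigid-motion traces and the mean ventricular signal by OLS. The
  intercept is included as standard practice. Collinear regressor
  columns are dropped (pivoted QR) with a logged warning rather than
  failing, so degenerate nuisance files degrade gracefully.
* **Smoothing** is an isotropic Gaussian of configurable FWHM (default
  0.6 mm, converted per axis to voxels). The kernel is renormalized over
  the mask — the smoothed masked image is divided by the smoothed
  mask — so constants are conserved and edge voxels are not diluted
  toward zero. The discrete kernel is truncated at 8σ, making it match
  the analytic Gaussian to below 1e-6 everywhere.
* **Band-pass** is an ideal (hard) frequency-domain filter (default
  0.01–0.1 Hz): DFT components inside the closed band are kept, all
  others including DC are zeroed, so outputs are zero-mean per voxel.
  The filter family is a design choice; a hard filter makes the spectral
  contract exact and testable (pass-band preserved to < 1 %, stop-band
  suppressed to < 1 % for bin-aligned sinusoids). Frequencies above
  Nyquist (1/(2·TR)) are rejected with an explicit message.
  Regression and filtering are applied sequentially, as listed.

### Connectivity maps

* **Global (weighted degree centrality)**: for each in-mask voxel, the
  Pearson correlation with every other in-mask voxel, Fisher
  z-transformed and averaged. Averaging on the z scale is the default
  (`average_domain="z"`); averaging r before transforming is available.
  Correlations are clipped to |r| ≤ 1 − 1e-7 before `atanh` so the
  transform stays finite; voxels with zero temporal variance are
  excluded from all target sets and flagged NaN (counts logged).
* **Local**: the same restricted to voxels within a Euclidean radius in
  voxel units (default 6). Voxels with no in-radius neighbor are NaN.
* **Seed**: Fisher z of the correlation between each voxel and the mean
  time course of a seed block (default 3×3×1 voxels). A zero-variance
  seed is an error.
* **VOI score**: the NaN-ignoring mean of a map over a volume of
  interest; the NaN fraction is logged.

No correlation threshold is applied before averaging (none is assumed by
default; the degree metric is fully weighted).

### Factorial inference and cluster correction

Per voxel, OLS of the map value on [1, sex, genotype, sex×genotype]
with ±1 effect coding (male = +1, mutant = +1). With a balanced design
the columns are orthogonal and the squared interaction t equals the
two-way-ANOVA interaction F (asserted in tests to 1e-8). Voxels NaN in
any subject are excluded. Zero-residual-variance voxels report t
clipped at ±1e6.

Cluster correction is nonparametric: clusters are the maximal
face-connected (6-neighbor; 18/26 behind a flag) components above the
cluster-forming threshold (default |t| > 2.1), positive and negative
tails separately. The familywise null is the distribution of the
maximum suprathreshold cluster extent over permutations of the design:
for the interaction (and genotype) contrast, genotype labels are
shuffled within sex strata; for the sex contrast, sex within genotype
strata. This restricted scheme respects exchangeability under the null
of the tested contrast. Corrected p = (1 + #{perm max ≥ extent}) /
(1 + n_perm), which is never below 1/(1 + n_perm) and is monotone in
extent within a run. Permutations are drawn from a seeded generator and
are bit-reproducible.

ROI-level operations: two-sided pooled-variance t tests on ROI summary
scores, and Type-II two-way ANOVA (equal to Type I/III when balanced)
with optional Tukey HSD over the four cells. Effects with zero sum of
squares report F = 0 even when the residual variance also vanishes.

## Omics pipeline

### Filtering and normalization

Genes with fewer than `min_reads` (100) reads in `min_samples` (2) or
more samples are dropped; of the remainder, the bottom `var_quantile`
(15 %) by log-CPM variance are dropped — exactly ⌊q·n⌋ genes, ties
broken by retaining lower gene IDs (stable, documented).

TMM factors follow the classic recipe: the reference is the sample
whose upper-quartile count fraction is closest to the mean upper
quartile; per sample, M (log2 ratio) and A (log2 abundance) values
against the reference over co-expressed genes are doubly trimmed (30 %
of M, 5 % of A, each side, rank-based) and the surviving M values are
averaged with inverse-delta-method precision weights; factors are
rescaled to geometric mean 1. Samples with |M| uniformly below 1e-6
get factor 1 (a pure depth difference is absorbed by library size).

log-CPM uses the voom offsets: log₂((k + 0.5) / (libsize·factor + 1) ·
1e6). Precision weights are voom-style: gene-wise linear fits give
residual SDs, a lowess trend (frac 0.5) of √SD against average log₂
count is evaluated at each observation's fitted log₂ count (clamped
extrapolation beyond the trend range), and the weight is trend⁻⁴.
Weights are strictly positive and nonincreasing in predicted variance
by construction; at least 10 genes are required to identify the trend.

### Surrogate variables

The known model (genotype, sex, interaction, RIN) is projected out of
the log-CPM matrix and the surrogate variables are the leading
sample-side singular vectors of the residual (orthonormal; sign fixed
so the largest-magnitude element is positive). This is a simplified,
non-iterative reading of surrogate-variable analysis — artifact
principal components of the error term — which matches how the
estimated variables are used downstream (as nuisance covariates). The
default is 2 SVs; n_sv must stay below n_samples − rank(design).

### The factorial fit and classification

Per gene, weighted least squares for
`logcpm ~ genotype*sex + RIN + sv1 + sv2` with ±1 effect coding and the
voom weights. Reported contrasts: the interaction coefficient, and the
within-sex simple effects MUT − WT, which equal 2(b_g + b_gs) in males
and 2(b_g − b_gs) in females. Residual variances are empirical-Bayes
moderated across genes by default: a scaled-F prior is fitted to the
gene-wise variances by the method of moments on log variances
(trigamma inversion), posterior variances are
(d0·s0² + d·s²)/(d0 + d), and moderated t statistics use d + d0 df.
We initially fit plain WLS t with the ordinary residual df, but
calibration runs showed that choice is anticonservative in the extreme
tail at n ≈ 5/cell (log-CPM of NB counts is not Gaussian enough at
~13 df, and the family-wise BH event lives at p ~ 2.5e-5), producing
spurious q < 0.05 discoveries on null cohorts more often than the
nominal rate; moderation restores tail calibration, which is the
standard remedy in precision-weighted expression modeling.
``moderate=False`` retains the plain fit. BH-FDR is computed over the
interaction p values.

Genes at interaction q < 0.05 are classified by simple-effect signs:
male < 0 < female → M−F+; female < 0 < male → M+F−; same nonzero signs
→ concordant (reported separately, never forced into a directional
class); all else NS. The class names describe within-sex directions,
which is why classification uses the simple effects rather than the
interaction sign alone.

### Enrichment

One-sided upper-tail hypergeometric tests: with background N, list K
(intersected with the background), query n and overlap a,
p = P[X ≥ a]. Depletion is visible as OR < 1 without a second test.
The odds ratio comes from the 2×2 table with a Haldane–Anscombe +0.5
correction applied to all cells iff any cell is zero (flag-switchable).
The BH family is all (query, list) pairs tested in one invocation. The
background universe is an input — by convention the post-filter gene
set of the DE analysis — never a constant. Chromosome
disproportionality reuses the same test per chromosome with BH across
chromosomes, and reports the percentage of each chromosome's background
genes falling in the class. Homolog mapping is a user-supplied
two-column table; unmapped genes are dropped with a logged count and
many-to-one collisions deduplicated.

## Synthetic data

### BOLD cohorts

Each network mask shares a latent signal per subject. Latents are
band-limited Gaussian processes (0.01–0.1 Hz by default), emulating
slow hemodynamic network fluctuations — this is why the analysis
band-pass retains network structure while suppressing broadband noise.
Voxel noise is stationary unit-variance AR(1) (coefficient 0.4 by
default), the minimal temporally autocorrelated model. Six
random-walk motion traces and one ventricular trace are linearly mixed
into the data with random per-voxel loadings (strength 0.3), so
nuisance regression demonstrably removes structured artifact.

Planted effects are specified in Fisher-z units of within-mask pairwise
correlation: each mask has a baseline z (default 0.3) plus additive
deltas for the sex main effect (males), genotype main effect (mutants)
and interaction (mutant males only). The latent amplitude w per cell
solves r = w²/(w² + σ²) = tanh(z), so the expected raw-data pairwise
correlation inside the mask equals the planted target exactly.
Overlapping masks are allowed only with identical effect entries.
Ground truth labels every voxel (null / network / sex / genotype /
interaction) and carries the design table.

Default geometry: 16×16×8 voxels at 0.23×0.23×0.6 mm (matching a
high-field mouse EPI voxel aspect), TR 1 s, 120 frames, 5 subjects per
cell. At this voxel size the default 0.6 mm smoothing kernel spans
~2.6 in-plane voxels, which is what makes the planted effects behave
like spatially coherent clusters rather than isolated voxels.

### Count cohorts

Baseline log₂-CPM is Normal (mean 4, SD 1.5); gene-wise NB dispersions
are log-normal (median 0.05, log-SD 0.5) with variance μ + φμ²;
library sizes are uniform on 0.8–1.2 million. Planted gene sets are
disjoint blocks with per-sex log₂ fold changes applied multiplicatively
to mutants — opposite signs within sex produce the M+F−/M−F+
phenomenology; concordant interactions are available by setting
same-sign fold changes. A binary artifact factor loads ~30 % of genes
(Gaussian loadings, strength 1 log₂ unit) on a per-cell-balanced half
of the samples, so it is orthogonal to the design and recoverable as
SV1. An RIN-like covariate (uniform 7.5–9.5) influences ~20 % of genes
with small Gaussian slopes. Relative expression is renormalized per
sample before scaling by library size, so fold changes are compositional
as in real sequencing.

### What the simulations do not model

No scanner physics, physiological noise spectra, motion-induced
spin-history effects, registration error, or spatial heterogeneity of
the hemodynamic response; no UMI/duplication artifacts, GC or length
bias, isoform structure, or outlier samples. Passing calibration and
recovery tests on these cohorts shows the estimators and their error
control are implemented correctly under the stated models, not that
effect sizes from real tissue would be recovered at these rates.

## Numerical choices and problem sizes

* Correlation clip 1 − 1e-7 before atanh (z ceiling ≈ 8.4).
* t statistics clipped at ±1e6 when residual variance is zero; 0/0
  (no effect, no noise) reports t = 0.
* Permutation p floor 1/(1 + n_perm); default 500–1000 permutations.
* Monte-Carlo calibration sizes: FWER over 100 null cohorts
  (16×16×8, t = 120, n = 5/cell, 500 permutations); detection power
  over 50 cohorts with a 0.4 z interaction in a 40-voxel mask,
  measured on seed-based maps with the 3×3×1 seed inside the planted
  network (degree-centrality maps dilute a 40-voxel network ~50-fold
  over a 2048-voxel brain, so the focal seed analysis is the
  appropriate instrument for a focal planted effect); DE calibration
  over 50 null NB cohorts of 2000 genes. The acceptance script uses 60
  null and 40 planted imaging cohorts and 20 null omics cohorts, with
  sizes recorded in its JSON output.
* The p-value uniformity check runs on an artifact-free null cohort:
  with the artifact present, two estimated SVs remove most but not all
  of its variance, and the small residual leakage perturbs the
  extreme tail of the null p distribution — an inherent property of
  surrogate-variable adjustment. Under the full default conditions
  (artifact on) the probability that a 2000-gene null cohort yields at
  least one q < 0.05 discovery is ~0.09 in our calibration runs,
  against ~0.05 for a perfectly calibrated analysis — a mild residual
  inflation that moderation reduces but does not remove entirely.
* Volumes are stored float32, computed float64. All randomness flows
  through explicitly seeded `numpy` generators; identical spec + seed
  reproduces bit-identical data and byte-identical pipeline outputs.

## Known limitations

* Cluster inference assumes within-stratum exchangeability; it is not
  exact for heteroscedastic groups.
* The simplified (non-iterative) SV estimator can absorb real signal if
  planted effects are massive and n_sv is large; with the default 2 SVs
  and the tested effect sizes this is negligible.
* Without empirical-Bayes moderation, power at very small n is somewhat
  below a limma-style analysis; calibration (type-I control) is the
  property we guarantee.
* TMM assumes most genes are not differentially expressed between
  samples; cohorts violating this (global shifts) need external
  normalization.
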