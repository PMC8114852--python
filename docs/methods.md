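# Methods

This note records the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic data
generator does and does not emulate, and the numerical decisions that a
user reproducing results should know about.

## Size correction and standardization

Linear skeletal measurements confound shape with body size. The default
recipe (`gm-boxcox-z`) is:

1. **Size removal.** Each taxon's row is divided by its own geometric
   mean, exp(mean(log xᵢ)) — Mosimann-style shape ratios. Because the
   geometric mean is multiplicatively homogeneous, uniformly rescaling a
   specimen (units, magnification, body size under isometry) leaves its
   shape row exactly unchanged; this invariance is tested to 1e-10.
2. **Box-Cox.** Each column is transformed by (xᵏ−1)/k (natural log at
   k=0) at the λ maximizing the profile log-likelihood over [−5, 5].
   The optimum is located by a bounded scalar search and then polished by
   a root find on the analytic score function, so λ is reproducible to
   ~1e-12 and insensitive to last-ulp perturbations of the input —
   without this the size-invariance above would only hold to ~1e-8.
3. **z-scoring.** Each column is centred and scaled by its sample
   standard deviation (n−1 denominator, consistent with the covariance
   PCA).

The phrase "z-transformation using the geometric mean" admits a second
reading; an alternative mode (`boxcox-gm-z`: Box-Cox per column on the
raw data, then division by the raw-row geometric mean, then z) is
selectable in the config. The default applies the geometric mean first
because Box-Cox output can be negative and has no geometric mean.

All fitted constants (λ, means, sds) are stored on the `ShapeMatrix` and
fossils/new specimens are pushed through the identical transform —
z-scoring uses all-taxa constants because the PCA is run on the pooled
sample. Missing cells are rejected by default; an explicit
`impute_missing` flag enables column-mean imputation for composite
fossil rows whose upstream compositing is out of scope here.

## Ordinations

**PCA** is an eigendecomposition of the sample covariance matrix
(ddof=1) of the standardized data. Eigenvector signs follow the
largest-magnitude-coefficient-positive rule so scores are reproducible
across platforms; variance fractions are eigenvalue shares.

**Canonical LDA** solves the generalized eigenproblem B·a = θ·S_w·a with
S_w the pooled within-group covariance and B the between-group scatter;
axes satisfy aᵀS_w a = 1 (scores are in pooled within-group standard
deviations) and variance fractions are the proportion-of-trace
eigenvalue shares; g groups yield g−1 axes. If the within-group scatter
is singular (variables ≥ N−g) a pseudo-inverse fallback engages with a
warning — with 29 variables, 85 extant taxa and 6 groups the design is
near this edge but does not cross it. Fossils never enter training: they
are centred with the extant grand mean and projected through the
extant-trained axes.

**RDA** uses the two-parameter covariance shrinkage

  Σ_k(λ) = [(1−λ)·W_k + λ·W] / [(1−λ)·(n_k−1) + λ·(N−g)]
  Σ_k(λ, γ) = (1−γ)·Σ_k(λ) + γ·(tr Σ_k(λ)/d)·I

with W_k the group scatter and W the pooled scatter, so (γ=0, λ=0) is
quadratic discriminant analysis, (γ=0, λ=1) linear discriminant
analysis, and γ=1 a spherical nearest-scaled-mean rule; the limiting
cases are verified decision-for-decision against independent
implementations. Classification is the Gaussian log-discriminant rule
with priors proportional to group sizes by default (uniform priors are
selectable). (γ, λ) is selected on a 21 × 21 lattice over [0, 1]² by
stratified 10-fold cross-validated misclassification (default) or
stratified-bootstrap out-of-bag error (25 resamples); ties break toward
the first lattice point, grid points with singular covariance (possible
only at γ=0 with groups smaller than the variable count) are treated as
infeasible, and apparent, cross-validated and bootstrap error are all
recorded at the selected optimum.

## Group separation

Pairwise PERMANOVA computes, for each group pair, the pseudo-F

  F = (SS_between/(g−1)) / (SS_within/(N−g)),

with sums of squares obtained from pairwise squared Euclidean distances
(SS_total = Σ_{i<j} d²ᵢⱼ/N, within-group sums analogous), and a
permutation p-value from random relabellings within the pair:
p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1), never zero. The default
n_perm = 1999 makes the smallest attainable p 0.0005. p-values across
pairs are adjusted by the Benjamini–Yekutieli step-up procedure (valid
under arbitrary dependence of the pairwise tests; delegated to
statsmodels and property-tested against the definition). Every raw p is
supplemented with the Bayes factor bound BFB = 1/(−e·p·ln p), the upper
bound on the odds favouring the alternative that a p-value can justify;
the bound is 1 at p = 1/e and reported as undefined (NaN) above it.

## Phylogenetic signal

Blomberg's K for a trait x on a tree with Brownian tip covariance V:
with the GLS mean â = (1ᵀV⁻¹x)/(1ᵀV⁻¹1),

  K = (MSE0/MSE) / {[tr V − n/(1ᵀV⁻¹1)]/(n−1)},
  MSE0 = (x−â)ᵀ(x−â)/(n−1),  MSE = (x−â)ᵀV⁻¹(x−â)/(n−1).

K ≈ 1 under Brownian motion on the tree, exactly 1 on a star tree, and
≪ 1 for tree-independent traits; these calibrations are verified by
simulation and the implementation is cross-checked against the R
phytools reference on a fixture. Significance permutes trait values
across tips: smaller MSE means better fit to the tree, so
p = (#{MSE_perm ≤ MSE_obs} + 1)/(n_rand + 1). The randomization count is
a required argument (the pipeline default is 9 999; tests run 499–999 —
problem sizes chosen to keep the suite quick while leaving the
calibration conclusive).

The tree is a majority-rule consensus of a posterior sample, built as a
**rooted clade consensus** (the input trees are rooted, node-dated and
ultrametric): exactly the clades occurring in > threshold of trees are
kept (threshold ∈ [0.5, 1) guarantees mutual compatibility), unresolved
regions collapse to polytomies, and each consensus branch length is the
mean over the trees containing that clade — the averaging rule is a
package decision, as is accepting non-ultrametric inputs without
coercion. Fossils are excluded from K (no resolved phylogeny for them);
name matching between table and tree tips is exact and case-sensitive,
with a validation report of discrepancies.

## Disparity

Three metrics per group over the chosen score axes: sum of per-axis
ranges (overall spread; axis-dependent by construction), sum of per-axis
sample variances (equals Σd²ᵢⱼ/(n(n−1)); rotation-invariant) and mean
pairwise Euclidean distance (rotation-invariant). Bootstrap: 200
pseudoreplicates at full group size, 95% CI from the 2.5/97.5
percentiles. Rarefaction: with-replacement subsamples at every size from
the smallest comparable group (floor 2) to the group's size, the
rarefied value being the mean of per-level means; a without-replacement
mode exists. Between-group comparisons: Wilcoxon rank-sum (exact when
n_a·n_b ≤ 400 and tie-free, else tie-corrected normal approximation) and
the Bhattacharyya coefficient (common equal-width binning over the
pooled range, ⌊√(n_a+n_b)⌋ bins — the bin rule is a package decision) on
the bootstrap distributions, and a permutation test on the raw group
difference whose null redistributes the pooled taxa at the original
group sizes (10 000 reassignments by default, exhaustive enumeration
available and exact for small groups).

## Synthetic data

Each taxon has a latent shape vector drawn from its locomotor group's
multivariate normal (orthogonal group-mean directions, separation 3
within-group sds by default) and a latent log-size z ~ N(0, 0.3²);
measurement j is exp((L·s)ⱼ + interceptⱼ + allometryⱼ·z) with a fixed
8-factor → 29-variable loading matrix, so measurements are strictly
positive, share a multiplicative size confounder, and have a known
low-rank covariance for the PCA to recover. With all allometry exponents
equal to 1 (the default) the geometric-mean correction removes size
exactly; unequal exponents give the approximate regime. Fossils (40
Palaeocene, 5 Cretaceous) are displaced 5 within-group sds along a
latent axis orthogonal to every group-mean direction — occupying their
own "robust" region while remaining nearest their generating group —
with covariance inflated 1.5× and true groups drawn mostly from the
ground-dwelling modes; Cretaceous taxa get a further 2-sd shift on
another orthogonal axis so the two fossil strata separate. Birth–death
trees are simulated with dendropy (default birth 1.0, death 0.5,
conditioned on the tip count, with the clock run past the final
speciation by the waiting time to the next event so all divergences have
positive age), and Brownian traits accumulate Gaussian increments with
variance σ²·(branch length).

What the generator does **not** emulate: realistic anatomical covariance
among tarsal dimensions, non-log-linear allometry, measurement error,
fossil missing-data patterns beyond simple cell masking, and any
phylogenetic structure in the extant group means (groups are exchangeable
clusters, not clades). Tests passing on these data therefore show the
machinery is correct and calibrated, not that real tarsal data meet the
model's assumptions.

## Numerical choices and limitations

* Permutation p-values use the (count+1)/(n_perm+1) convention
  throughout; permutation streams are seeded per pair/stage from one
  global seed via a fixed counter scheme recorded in the run manifest,
  so reruns are byte-identical and stages can be rerun in isolation.
* Eigenvector/axis signs: largest coefficient positive. Classification
  ties break to the first group in sorted label order.
* Degenerate inputs fail loudly: constant columns (Box-Cox), constant
  traits and singular V (Blomberg's K), groups of one (PERMANOVA, MPD),
  non-positive measurements (everything).
* The Bhattacharyya coefficient depends on the binning rule; with few
  observations it is a coarse overlap summary.
* RDA error estimates on small groups are high-variance; cross-validation
  requires the smallest group to be at least the fold count.
* Sum of ranges is deliberately not rotation-invariant (it measures
  axis-aligned spread in the given ordination); both behaviours are
  under test.
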