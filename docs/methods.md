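# Methods

This note documents the models and procedures implemented in `geneclim`,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic-data generator does and does not emulate.

## Niche modeling: the small-model ensemble

With tens of occurrences and many climate predictors, a single multivariate
model overfits. The ensemble-of-small-models strategy fits every unordered
pair of predictors as its own presence/background classifier and averages
the member maps. Two learner families ship by default — an L2-penalized
logistic regression on linear + quadratic + interaction terms (C = 1,
features standardized on the training fold) and a random forest (200 trees,
minimum leaf 5) — with gradient boosting available behind the same learner
interface. More families change little once maps are ensemble-averaged.

Background design: 10,000 cells by default (or all cells when fewer are
available), sampled without replacement within the accessible (M) area with
probability proportional to a Gaussian kernel density of the occurrences
(Scott's-rule bandwidth unless given), floored at 1e-6 of its maximum so no
cell is unreachable. Matching background density to occurrence density
transfers spatial sampling bias from the presences to the background, so
the classifier learns environment rather than survey effort. Presence cells
are excluded from the background. The M area is the union of D8 watersheds
(steepest-descent flow on the DEM, basins labeled by terminal pit) that
contain at least one occurrence; a polygon can override it.

Validation is spatially blocked: occurrences are split at their median x,
then each half at its own median y, giving four geographic quadrant bins
whose occurrence counts differ by at most one; background points follow the
same cuts. Per model, AUC (Mann-Whitney rank estimator, midranks for ties)
and the Continuous Boyce Index (101 moving windows of width 0.1 of the
suitability range; Spearman correlation of the predicted-to-expected ratio
against window rank; window count and width are conventional, not
prescribed) are averaged over the four leave-one-bin-out folds. Models
below AUC 0.7 are excluded; the rest are weighted by AUC (weights
normalized to 1).

Binarization thresholds: maximize TSS (searched over midpoints of sorted
unique scores, ties resolved toward the lower, more inclusive threshold),
minimum observed presence, and the 10th percentile of occurrence
suitability with linear interpolation (so ten values 0.1..1.0 give 0.19).
The optional 200 m buffer is a morphological dilation with a Euclidean disc
over cell centers. MESS follows the standard percentile formula per
variable, taking the minimum across variables; constant reference variables
are excluded with a warning.

## Dispersal automaton

Future binary maps are constrained by an annual cellular automaton: each
year, a cell becomes occupied if it is suitable and its center lies within
the annual dispersal rate (Euclidean, center to center) of an occupied
cell. Suitability is held constant within each climate period (piecewise-
constant 30-year intervals); at a period transition, occupied cells that
lost suitability are vacated and can be regained only by dispersal, not
instantly on becoming suitable again. Initial occupancy defaults to the
current-period binary range. The automaton is deterministic; there is no
long-distance-dispersal stochasticity. Note the geometry of small discs: at
a rate of one cell per year the Euclidean disc is the von-Neumann (plus-
shaped) neighbourhood, so fronts grow at Manhattan, not Chebyshev, speed.

## Population structure

PCA mean-imputes missing dosages per locus, centers loci and
eigendecomposes; component signs are fixed by making the largest-|loading|
coordinate positive.

Admixture is a constrained matrix factorization of G/2: ancestry rows Q on
the probability simplex, ancestral frequencies F in [0, 1], minimizing the
squared reconstruction error over observed entries. Blocks are updated by
projected gradient steps of length 1/L (L the block Lipschitz constant:
the spectral norm of QᵀQ or FFᵀ), which guarantees a monotonically
nonincreasing loss — asserted in the tests. The sparsity regularization of
the original formulation is omitted (α = 0 by default): downstream stages
consume K and the hard cluster assignment, not shrunken coefficients. K is
selected by masked cross-entropy: per replicate, 5% of observed entries are
held out, the fit is scored by the negative mean log Binomial(2, [QF])
likelihood of the held-out dosages, and the K with the lowest mean across
replicates wins. Ten replicates is the default; five are already enough for
reliable selection on the test fixtures.

Genetic distance is D = 1 − ps, with ps the mean shared-allele proportion
over loci genotyped in both individuals (identical homozygotes 1, het vs.
anything 0.5, opposite homozygotes 0). The literal reciprocal 1/ps is
available by flag but not default: it is unbounded and lacks a zero
diagonal, while 1 − ps is a bounded dissimilarity with the same ordering.
The Mantel test correlates upper triangles and permutes rows/columns of one
matrix jointly; the default alternative is one-sided positive, matching the
isolation-by-distance hypothesis.

## Genotype-environment association

Two imputations feed the two detectors: low-rank matrix completion
(iterative truncated SVD with observed-entry restoration, rank 5, clipped
to [0, 2]) for the latent-factor tests, and within-cluster locus means
(clusters = admixture assignment, global-mean fallback) for the RDA.

The latent-factor test ridge-projects the environment out of the genotype
matrix (λ = 1e-5), takes the first K = 5 left singular vectors of the
residual as latent factors, and regresses each locus on [intercept,
environment, factors] by OLS. Per climate variable, z-scores are
recalibrated by the genomic inflation factor λ_GIF = median(z²)/0.4549 (the
exact median of χ²₁), p-values come from χ²₁ of z²/λ_GIF, and
Benjamini-Hochberg runs per variable across loci; a locus is a candidate at
q ≤ 0.05 for any variable. Tests are per-variable rather than omnibus
because downstream reporting counts candidates per climate variable.

RDA standardizes the environment (constants stored for later projection),
centers genotypes, regresses Y on X and eigendecomposes the fitted values.
Eigenvalues partition the constrained inertia; the first three axes are
retained. SNP loadings are standardized per axis and loci beyond 2.5 SD on
any retained axis are outliers; each is assigned the climate variable with
the largest |Pearson r| to its dosage (the assignment rule is a
convention — biplot angle would be an alternative). Axes are oriented so
the largest-|coefficient| predictor is positive, making every projection
sign-reproducible. The final candidate set is the intersection of the two
detectors, a deliberately conservative rule.

## Adaptive units and genetic offset

The candidate-SNP RDA is refitted on the joint candidates only, and
*individuals* (site scores on the three retained axes) are clustered —
units of individuals, not of SNPs, are what can be mapped and managed.
k-medoids (PAM: greedy build, swap refinement) and Ward agglomerative
clustering both run for k = 2..6; each solution is scored by
S = A1 + A2 with A1 the mean silhouette width and A2 the Calinski-Harabasz
statistic min-max rescaled to [0, 1] across the candidate solutions. The
concrete A1/A2 pair is this package's choice of two complementary validity
indices (cohesion-based and separation-based); both are swappable. Exact
ties go to the larger relative S-improvement over the previous k. Solutions
containing a one-member cluster are discarded (a singleton is not a unit,
and silhouette is ill-behaved there); a winning silhouette below 0.35 flags
the assignment low-confidence.

A 500-tree random forest then predicts unit membership from the climate at
each individual's cell, scored by stratified cross-validation (10 folds,
reduced to the smallest class size when needed) with mean-decrease-Gini
importances, and is projected onto every binary-suitable pixel.

The genetic offset of a pixel standardizes its current and future climate
with the RDA's stored constants, projects both on the retained axes, and
takes offset = sqrt(Σ_k (w_k Δa_k)²) with w_k the eigenvalue *fraction* of
axis k among retained axes. Fractions rather than raw eigenvalues make the
offset invariant to genotype scaling; an unweighted variant is a flag. The
offset is a metric in the weighted axis space: zero iff the climate is
unchanged, symmetric, and linear under scaling of the climate shift.

## Synthetic data: what it emulates, and what it does not

Each climate variable is a Gaussian random field (Gaussian-kernel smoothing
of white noise, correlation scale 800 m on the default 60×60 grid of 100 m
cells — sub-km autocorrelation as expected for topoclimate at this
resolution) plus a linear gradient in a per-variable random direction, so
the predictor set behaves like one that already passed a collinearity
screen. The future period adds a constant shift (default +1.5 SD by
"2070"). True suitability is the product of Gaussian response curves with
breadth 0.5 SD per variable, rescaled to [0, 1]; this breadth makes the
true presence/background separability (AUC ≈ 0.75-0.85 against the
density-weighted background) comparable to what well-performing niche
models achieve on real range-restricted species. Occurrences are cells
sampled without replacement with probability proportional to suitability.

Genotypes: individuals are scattered uniformly and assigned to demes by
nearest deme center (Voronoi), so demes are spatially coherent yet every
deme samples a range of environments — individual-based sampling along
gradients. Neutral deme frequencies follow the Balding-Nichols model at
Fst 0.08 (microgeographic differentiation of a continuous amphibian
population); isolation by distance is induced by three smooth spatial
factors acting on logit frequencies with low-rank loadings (scale 0.3).
Adaptive loci ignore deme structure: the alt-allele probability is
logistic(a + b·z) with b = 4 on the standardized driver variable, drivers
assigned round-robin across variables. Genotypes are Binomial(2, p) with
5% missing entries. All randomness derives from one PCG64 generator;
landscape, genotypes, occurrences and missingness use independent streams
split by `SeedSequence.spawn`, so each stage is reproducible in isolation.

Not emulated: linkage between loci, coalescent/pedigree structure,
selection-migration dynamics, temporally varying selection, genotyping
error, and real topography (the DEM used in M-area tests is synthetic).
Passing tests therefore demonstrate correctness of the estimators under
the generating model, and calibration under exchangeable nulls — not
robustness to every property of real reduced-representation data.

## Numerical conventions and scale of the test problems

Grids are row-major, origin upper-left, half-open cell intervals; cell
membership uses centers. Rasters exchange as ESRI ASCII grids, chosen as a
plain-text, GDAL-standard raster format. Percentiles use linear
interpolation. Occurrence rarefaction keeps the first record per cell by
file order (seeded random choice by flag). The collinearity screen samples
at most 50,000 non-nodata cells (seeded) and drops, from the worst pair,
the variable with the larger mean |r| to all remaining variables.

The test and acceptance workloads run the full default fixture (60×60
cells, 6 variables, 40 individuals, 2000 loci) for parameter recovery,
20 replicate studies for detection power, 100 null studies for association
calibration and 500 for the Mantel size check — sizes chosen so the entire
suite completes in about a minute on one core while keeping Monte-Carlo
error well inside the asserted margins.

## Known limitations

* The latent-factor detector shows genome-wide inflation when neutral
  structure is strongly collinear with climate (few, environmentally
  distinct sampling sites); the GIF correction recovers calibration on
  exchangeable nulls but cannot fully separate structure from environment
  when they are confounded by design.
* MigClim-compatible behaviour is approximated at the level of the rule
  set (annual steps, Euclidean neighbourhoods, vacate-on-unsuitability);
  propagule pressure, maturity lags and barriers are not modeled.
* The watershed labeling is a plain D8 on cell centers without pit
  filling; heavily flat or hydrologically complex DEMs should use the
  polygon override.
* Admixture replicates use random initializations; with very few
  replicates the cross-entropy K choice can wobble on weakly structured
  data (five or more replicates were reliable on the fixtures).
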