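# Methods

## The prediction model

All prediction engines are built on one linear mixed model per trait:

    y = X b + Z u + e,     u ~ N(0, G sigma_u^2),     e ~ N(0, I sigma_e^2)

where `y` holds per-line adjusted phenotypes, `X` is the fixed-effect design
(an intercept, plus raw 0/1/2 allele-dosage columns for any markers fit as
fixed effects), `u` is the vector of random line effects, and `G` is the
VanRaden method-1 genomic relationship matrix

    G = W W' / (2 * sum_j p_j (1 - p_j)),

with `W` the dosage matrix column-centered by twice the observed
alternate-allele frequency `p_j`. With no marker fixed effects the model is
standard RR-BLUP/GBLUP. When up to four markers enter `X`, those markers are
also removed from the computation of `G`, so their signal is carried entirely
by the unshrunk fixed coefficients.

Variance components are estimated by REML. A single eigendecomposition
`G = U S U'` turns every restricted-likelihood evaluation into O(n) diagonal
algebra, and the variance ratio `lambda = sigma_e^2 / sigma_u^2` is profiled:
the search runs a 100-point grid over `log10(lambda) in [-5, 5]` followed by
bounded golden-section refinement (relative tolerance 1e-8). Both variance
components are recovered from the profiled closed form and are non-negative
by construction. A ridge of 1e-6 is added to `G + lambda I` inside linear
solves used for prediction, never to the stored matrix and never to the
small GLS systems of the likelihood profile (the profile must match the
brute-force restricted likelihood exactly; the test suite checks this
against an independent full-matrix implementation on a 0.1%-resolution
grid).

GEBVs for unphenotyped lines are the BLUP conditional mean under the joint
(training + target) relationship matrix,
`u_target = G[target, train] (G[train, train] + lambda I)^{-1} (y - X b)`,
plus the fixed-marker contribution `X_target b`. An algebraically identical
marker-effect ridge formulation (`a = (W'W + lambda c I)^{-1} W' (y - X b)`
applied to centered target dosages) is implemented as a second code path;
the two are required to agree to 1e-6 by the acceptance suite, which
licenses using either depending on whether targets are known at fit time.

## Heritability

Narrow-sense h2 is the additive genetic variance over the total phenotypic
variance, from an intercept-only REML fit on per-line adjusted values. The
additive variance among lines is `sigma_u^2 * mean(diag(G))`: with VanRaden
scaling on fully inbred material the mean diagonal is about `1 + F ≈ 2`, so
reporting the raw ratio `sigma_u^2 / (sigma_u^2 + sigma_e^2)` would
understate h2 by roughly that factor (0.4 would read as ~0.25). For a G
standardized to unit mean diagonal the two forms coincide. Parameter
recovery at targets {0.2, 0.4, 0.6} (n = 300, m = 2000, 20 reps) is held to
a mean absolute bias of 0.07.

## GWAS and fixed-effect selection

The association scan fits each marker as one extra fixed column in the
mixed model and applies a Wald test (chi-square, 1 df). Two modes:

- `exact_per_marker` (default): `lambda` re-optimized by REML for every
  marker;
- `p3d`: `lambda` fixed at the null-model estimate, which reduces the scan
  to vectorized weighted least squares (one matrix product per fold). The
  two modes agree on p-value ranking at Kendall concordance above 0.95 on
  family-structured simulations, so the fast mode is used inside replicated
  cross-validation experiments where thousands of scans are run; single
  analyses default to the exact mode.

P-values are Benjamini-Hochberg corrected across all tested SNPs *before*
binning. SNPs are then binned per chromosome into half-open 500 kb windows
anchored at position 0, keeping the lowest-P SNP per window: in breeding
populations with long-range LD an association peak typically spans a whole
window, and the window representative stands in for the peak. The bin width
is a parameter; populations with shorter LD need smaller bins.

Fixed-effect candidates are the up-to-three most significant peaks with
q <= 0.1 for the focal trait (if none pass, the single lowest-P peak is
carried as a fallback), optionally plus the single most significant peak
for a secondary flowering-time trait — flowering differences shift most
agronomic traits, so controlling for the top flowering SNP is offered as a
config toggle and is off for the flowering trait itself. All non-empty
subsets of the candidates (at most 15) are scored by OLS on training data
only; the score is the Pearson correlation of fitted values with the
training phenotype. Because that correlation is monotone under subset
inclusion, correlations within 1e-9 of the maximum are treated as tied, and
ties resolve to fewer markers, then lower mean q. The selected set reports
both the mean and the minimum corrected P of its markers; the model is
recommended over plain RR-BLUP when `-log10(min q) >= 2.0`, and the
recommendation flag is attached to every cross-validation result.

The MLR control (a non-genomic-selection baseline) ranks markers by
single-marker-regression F-test P-values, fits OLS models on the top
1..min(100, p) markers, and keeps the model with the best training-data
adjusted R^2 — plain R^2 would always pick the largest model.

## Cross-validation design

Folds are built from the genotypes, not at random: partitioning around
medoids (PAM: greedy BUILD plus best-improvement SWAP, Euclidean distance on
imputed dosages) is run for each candidate k, the k with the largest average
silhouette width wins (ties to smaller k; the default grid is coarse with a
±4 refinement around the optimum), and every cluster is assigned whole to
one of five folds — largest clusters first, each onto the currently smallest
fold, with seeded shuffling among equal sizes. Close relatives therefore
never face each other across the train/validation split, which would
otherwise inflate accuracy.

Training follows CV1 semantics: the validation cell's phenotypes (minus the
validation individuals) may join the training composite. Per-line adjusted
values are least-squares means of the two-way model `value ~ line + rep`
within each site x year x season cell (reducing to plain line means for
unreplicated data), averaged across the cells of the training composition —
the single-random-effect solver models one record per line, so multi-cell
information enters through this two-stage line-mean route. For the de novo
GWAS method the scan, binning, and subset search are redone per fold on
training-fold lines only, using the phenotypes of a designated GWAS source
cell; the kinship for the fold GWAS is rebuilt from training-fold lines.
The subset search scores candidates against the same composite training
vector the prediction model is fit to. Accuracy is the Pearson correlation
of predicted GEBVs with the adjusted validation-cell phenotype, averaged
over folds. Every run records a leakage audit (training and GWAS line sets
versus the validation fold) in its result object.

## The synthetic study

The generator emulates an elite inbred breeding program: inbred founders
with alternate-allele frequencies U(0.05, 0.5), biparental families, and
single-seed descent under the Haldane map (recombination fraction
`r = (1 - exp(-2d))/2`, no interference) for six selfing generations, so
residual heterozygosity is ~2^-6 and LD decays over family-sized blocks.
Defaults: 80 families x 4 lines (320 lines), 12 chromosomes of 30 Mb, 3000
markers, 1.5 expected crossovers per chromosome per meiosis. Three default
traits span the canonical architectures: two 15%-PVE QTL plus a 10%
polygenic background (flowering-time-like, h2 = 0.4), purely polygenic at
25% (yield-like), and one 10%-PVE QTL plus 20% polygenic
(plant-height-like). Phenotypes cover one site x two years x two seasons
with genetic correlation 0.7 across cells, two reps (rep noise sd 0.5), and
10% of line x cell blocks masked whole — mimicking how storms or pests
erase a line's entire plot record, not scattered missing values. Line-level
phenotypic variance is normalized to 1 per cell so PVE fractions read
directly as heritability contributions. Large-QTL effects are held stable
across environments (major genes mostly are); environment specificity is
carried by the polygenic term.

What the simulations do not contain: coalescent-realistic short-range LD,
selection during line development, dominance or epistasis, genotyping
error, and subpopulation admixture. Passing tests therefore demonstrate the
statistical machinery and the architecture-dependent ordering of methods,
not performance on any particular real population.

## Problem sizes in the test suite

Replicated experiments run at n = 200-320 lines and m = 300-10,000 markers
with 10-20 replicates per claim — sizes chosen so each simulated study
still exhibits the family structure, LD, and heritability regime of a real
breeding panel while the whole suite completes in a few minutes. The
fast P3D scan is used inside replicated CV experiments; the exact
per-marker scan is used wherever a single GWAS is the object under test.

## Known limitations

- Multi-cell training data are reduced to per-line composites; a
  multi-environment covariance model (explicit GxE) is out of scope.
- When no SNP passes FDR, the fallback lowest-P SNP carries a
  winner's-curse-inflated coefficient; on purely polygenic traits this
  costs a small amount of accuracy (the applicability rule exists exactly
  to flag such traits), and the cost grows if the GWAS source cell, the
  training composite, and the validation cell are all the same data.
- PAM clusters recover simulated full-sib families imperfectly (~50% of a
  sib pair's genome differs); the fold design guards against the closest
  relatives, not all relatedness.
- The BH q-values assume the marker-wise Wald p-values are well calibrated;
  strong unmodeled structure would propagate into candidate selection.
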