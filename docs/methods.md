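# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Genotype handling

Genotypes are alt-allele counts (0/1/2, −1 missing) for biallelic SNPs.
Filtering applies three stages in a fixed order — sample missingness,
locus missingness, physical thinning — with *strict-greater* cutoffs
(a sample at exactly 60% missing is kept) and greedy left-to-right
thinning per chromosome (keep a locus iff it is more than 300 bp from
the last kept locus). The defaults (0.60, 0.60, 300 bp) are the values
used throughout; thinning is idempotent by construction.

Genomic distance is Euclidean over pairwise-complete loci, rescaled by
sqrt(L/L_shared) so samples with different missingness remain on one
scale; this matches common practice for distance computation on
incomplete genotype matrices and avoids imputation. Geographic
distances are great circles on a sphere of the authalic radius
6371.0087714 km.

## Weir–Cockerham F_st

Per locus, the 1984 analysis-of-variance components a, b, c for r
populations of diploids, combined multilocus as a ratio of sums over
loci polymorphic in the populations compared. The estimator requires at
least one called genotype per population and three in total at a locus;
single-locus and low-divergence estimates may be slightly negative and
are retained — truncating before the unit-interval scaling would
distort the response entering the dissimilarity model. The scaling maps
off-diagonal values by v → (v − min)/(max − min), the only reading of
"subtract the minimum, divide by the maximum" that guarantees [0,1];
this interpretation is recorded here deliberately.

## PCoA and the Mantel test

PCoA is classical scaling (double-center −D²/2, `eigh`, coordinates
from positive eigenvalues; percent variance over positive eigenvalues
only). The Mantel test correlates lower triangles, permutes rows and
columns of one matrix simultaneously, and is one-sided for positive
association, p = (1 + #{r* ≥ r}) / (n_perm + 1) with 9,999 permutations
by default. Geographic distances are ln-transformed with co-located
pairs floored at 1 m (0.001 km) so the log is defined; the floor is
metadata, not a tunable. An exact mode enumerates all n! permutations
for small matrices and is the oracle used in the tests.

## The dissimilarity model

Monotone I-splines are integrals of order-2 (piecewise-linear)
M-splines; K basis functions place knots at evenly spaced quantiles of
the observed values (min/median/max for the default K = 3), each rising
0 → 1 over its support. The geographic basis forces its lower knot to
0 km so a zero-distance pair maps to a zero basis vector. Out-of-range
evaluation clamps to the training range and counts the clamps —
extrapolating a monotone spline beyond its knots is undefined, and
projection rasters routinely exceed site ranges.

The fit minimizes squared error on the response scale under the
negative-exponential link, subject to all coefficients ≥ 0: zero-
initialized Gauss–Newton where each iteration linearizes mu and solves
a non-negative least-squares subproblem, with step-halving if a step
would increase the deviance; convergence when the deviance improves by
< 1e−10, cap 100 iterations. The procedure is deterministic and, on
one-predictor problems, lands within grid tolerance of a dense
(beta0, beta) grid search. Deviance explained is 1 − D_model/D_null
with D_null from the best intercept-only fit (mu = mean response). A
near-constant response (null deviance ≤ 1e−12 of the response scale)
sets a degenerate flag and reports 0. The reference GDM literature uses
a likelihood deviance; the squared-error deviance used here is monotone
equivalent for fitting but numerically different, so deviance-explained
values are not comparable across implementations — both definitions are
documented, equality is not claimed.

Variable selection follows three sequential stages: (1) drop candidates
whose single-variable model (with geography) explains < 5% deviance;
(2) among survivors, while any pair of raw site-value vectors has
|Pearson r| > 0.60, drop the member of the most-correlated pair with
the lower single-variable deviance; (3) permutation importance on the
joint model (permute one variable's site values, rebuild pairs, refit;
importance = mean percent drop in deviance explained; p with the +1
correction). Stage 3 *flags* weak variables (p > 0.05 or importance
below a floor, default 1%) for analyst review rather than removing
them — the original workflow removed variables at this stage partly by
judgment, and judgment is not automated here; automatic removal is
available behind a flag. Cross-validation holds out ⌈30%⌉ of sites,
fits on training pairs only (bases rebuilt from training values),
predicts test-site pairs, and scores Pearson r; iterations with a
constant observed or predicted test response are excluded and counted.

## Landscape projection

`transform_environment` maps each predictor layer cellwise through its
fitted partial spline. Two geographic layers evaluate the geographic
spline on each cell's easting/northing offset (km) from the mask's
west/south edge — a per-axis approximation of the distance-based
geographic term that mirrors coordinate-transform practice for GDM map
projection; it is an approximation and is labelled as such. The PCA
RGB map is computed over in-mask cells, channels rescaled min → 0,
max → 255. Whether the geographic layers enter the PCA is switchable
(default: included).

Genomic vulnerability is the predicted dissimilarity between a cell's
current and future environments at zero geographic distance,
1 − exp(−Σ_p |f_p(x_cur) − f_p(x_fut)|); seed-source maps replace one
side with the target's future environment and add the geographic spline
at the target–cell distance. Both **exclude the fitted intercept** by
default: beta0 encodes the baseline dissimilarity of two distinct
samples, which would put a constant floor under same-location
comparisons; `include_intercept=True` restores it. Because the partial
functions are monotone, Σ_k beta_pk |ΔI_k| = |Δf_p| exactly, so the
pair-table form and the |Δf| form coincide. Nodata propagates through
any predictor; grids must be co-registered (no silent resampling).

## Phenotypes and Q_st–F_st

Relative height increment is (ln h2 − ln h1)/(t2 − t1) per day; values
above 0.035 are flagged as outliers, never auto-removed. Variance
components come from the two-level nested ANOVA by method of moments
with the unbalanced-design EMS coefficients (n0, n0′, nb); negative
estimates are truncated to zero and flagged. For maternal half-sib
families V_A = 4·sigma2_fam, hence Q_st = s_site/(s_site + 8·s_fam).
`variance_partition` is a sequential (type-I) fixed-effects
approximation — condition, site, line-in-site, residual — of what a
mixed model would partition; the order is fixed and documented because
sequential sums of squares are order-dependent.

The Q_st–F_st test compares Δ = Q_st − F_st (multilocus W-C theta over
the phenotyped sites) against a simulated neutral null: per replicate,
(a) loci are bootstrapped to draw F*; (b) the neutral among-site
variance is s_B* = [2F*/(1−F*)]·4·sigma2_fam; (c) estimation noise is
added by drawing each stratum **mean square** from its scaled
chi-square distribution and pushing the draws back through the same
moment equations (with truncation) used on the observed data — the
variance components themselves are not chi-square distributed, and
simulating them directly misstates the among-site sampling noise,
which is dominated by the subtraction of lower-stratum mean squares;
(d) Δ* = Q_st* − F*. The family and residual variances parameterizing
the null are nuisance values estimated by pooling all experimental
conditions (the family structure is shared across conditions), which
roughly doubles their degrees of freedom; with per-condition plug-ins
the null width is dominated by their estimation noise. The p-value is
two-tailed on |Δ| with the +1 correction (one-tailed behind a flag).
Locus bootstrap (rather than single-locus draws) is the resampling
unit. Analyses are per experimental condition.

Two calibration caveats, measured by the acceptance suite: (i) with six
sites the among-site stratum has 5 degrees of freedom, so ~20% of
neutral datasets truncate sigma2_site to zero — the statistic then has
a point mass at Δ = −F_st, and a statistic with an atom cannot have an
exactly uniform p-value (the atom maps to p ≈ 0.25–0.40, harmless at
any usable alpha; the continuous part is uniform); (ii) power against a
10× inflated site variance at the 6×6×8 design is near 0.8 — the
design, not the test, is the limit.

## The synthetic-data generator

Environmental layers are Gaussian random fields (seeded white noise
smoothed at the stated correlation length, standardized to mean 0,
sd 1); the future scenario adds a deterministic per-layer shift and
west–east gradient — tests need known offsets, not climate realism.
Sites are scattered uniformly with a minimum separation; the local-km
grid is mapped to WGS84 around (−35°, 147°) so great-circle distances
agree with grid kilometres.

Genotypes use a logit-normal frequency model: per locus an ancestral
frequency p0 ~ U(0.1, 0.9) receives site-level logit deviations from a
multivariate normal with covariance s²·exp(−eta), so differentiation
rises monotonically with the true dissimilarity predictor eta. This
was chosen over a Balding–Nichols beta model because it can express an
arbitrary *pairwise* covariance keyed to eta; the cost is that realized
F_st is calibrated empirically, not analytically. exp(−eta) need not be
positive semi-definite, so the diagonal is lifted by the most negative
eigenvalue (a few percent of extra site-independent noise that leaves
pairwise structure intact). The study-scale preset (36 sites, 3–10
samples/site, 9,378 loci, four drivers with weights 0.35/0.28/0.22/0.15
on a 1,280 km grid, geographic effect flat to 500 km, s² = 0.5) yields
mean pairwise F_st ≈ 0.04 with maxima near 0.08–0.10 at >1,200 km,
matching the differentiation regime the pipeline is designed for. The
6-site growth-experiment worlds use a 350 km minimum separation,
emulating range-spanning site selection.

Phenotypes are y = mean + condition + site + line + residual with
N(0, ·) effects; when the world targets neutrality, sigma2_site is set
from the realized genomic F_st through the same half-sib relation the
test inverts. Defaults sigma2_fam = 1, sigma2_res = 4 give the
family-dominated, mostly-unexplained variance structure typical of
seedling growth assays.

What the generator does **not** emulate: linkage disequilibrium,
individual-locus selection, coalescent ancestry, non-equilibrium
demography, genotyping error, or GCM-like future climates. Passing
tests therefore show the estimators and pipeline are correct under the
assumed covariance structure — not that real data meet it.

## Problem sizes and numerical policy

The test suite runs the oracle checks at hand size; recovery at the
full study scale (36 sites × 9,378 loci × 20 seeds); Mantel calibration
at 1,000 simulations × 999 permutations; Q_st–F_st calibration at 500
neutral datasets (null size 1,000) and power at 200 datasets; and the
threshold-recovery experiment with K = 5 basis functions — K = 3 places
its single interior knot at the median pairwise distance (~630 km), and
no non-negative combination of those three I-splines can be flat to
500 km while rising beyond it, so resolving the threshold is a basis-
resolution question, not a fitting one. K = 3 remains the default
everywhere else.

All stochastic operations take explicit seeds; the CLI derives each
stage's seed from a master seed by hashing the stage name. Floating-
point reductions use fixed (numpy) ordering, making end-to-end reruns
byte-identical on one platform.

## Known limitations

- The squared-error GDM deviance is not numerically comparable to the
  reference implementation's likelihood deviance.
- The per-axis geographic raster transform approximates a pairwise
  distance term; vulnerability and seed-source maps use true distances.
- Method-of-moments variance components are inefficient relative to
  REML for badly unbalanced phenotype designs; REML is out of scope.
- Raster I/O is text-based (ESRI ASCII grid + JSON sidecar); GeoTIFF
  is not produced.
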