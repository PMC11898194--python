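# Methods

This note documents the models and procedures `divfacets` implements, the
defaults and why they were chosen, what the synthetic landscape does and
does not emulate, and the numerical choices a user should know about.

## Community assembly

Assemblages are built on a regular grid of square cells (default 5 × 5 km)
in projected planar coordinates.  A species is present in a cell when its
extent-of-occurrence polygon overlaps the cell square with strictly
positive area; a boundary touch (zero-area intersection) does not confer
presence.  This tie-break avoids float-sensitive edge inflation; cell
squares are treated as half-open so each boundary point belongs to exactly
one cell.

Raw presences are then refined with per-species IUCN-style attributes:
cells whose elevation falls outside the species' `[elev_lo, elev_hi]`
(inclusive on both ends — the convention is not standardized, so we chose
the permissive one) or whose habitat code the species does not tolerate are
set to absence.  Refinement never creates presences, is idempotent, and
commutes with species subsetting.  Finally, species with any missing value
among the nine traits are excluded; the remaining pool is used for
richness, functional and phylogenetic diversity alike, so all three facets
describe the same community.

Cells with fewer than two species are retained in the matrix but flagged;
functional and phylogenetic diversity are undefined there.

## Diversity metrics

**Species richness** is the column sum of the (trait-filtered) presence
matrix and is the single source of richness truth downstream.

**Faith's PD** is the sum of branch lengths of the minimal subtree
connecting a cell's species *and the root* (root-inclusive, the classic
convention of the standard community-phylogenetics tooling, which we
cross-check against `picante::pd` in the test suite).  It is undefined
below two species, monotone under species addition, and equals the total
tree length when all tips are present.

**Functional richness (FRic)** is a convex-hull volume in a pooled
standardized trait space built once from the full retained species pool
(never per cell, so values are comparable across cells):

1. body mass and the three length traits are log10-transformed (mammal
   size traits are log-normal; configurable off);
2. every trait is z-scored with the n−1 SD;
3. the pool's principal axes (numpy SVD; volumes are rotation-invariant)
   provide the reduced space: a cell with $S$ species uses the leading
   $d = \min(S-1, d_{\max})$ axes, since a hull volume needs more points
   than dimensions.  $d_{\max}$ defaults to 9 (all traits); pipelines on
   large landscapes may set it lower (the worked examples use 4) because
   high-dimensional hull computation is the cost center of the null models.
   Values at different $d$ are not comparable, so $d_{\max}$ is fixed per
   run.

Degenerate point sets (coplanar after reduction) return volume 0 with a
flag rather than an error — randomized assemblages can legitimately be
degenerate and the null-model machinery needs a value.  FRic is undefined
below three species.

## Null models and standardized effect sizes

Null communities come from the Curveball algorithm: a trade picks two
distinct species uniformly, pools the cells held by exactly one of them,
and redeals that pool at random while keeping both species' occupancies —
which provably preserves all row and column sums.  Each of the `n_reps`
(default 999) replicates is an independent chain started from the observed
matrix with a replicate-specific child seed (embarrassingly parallel and
reproducible, rather than one long thinned chain).  Chain length defaults
to `max(5 × n_species, 1000)` trades: margin-preserving chains mix in the
order of the number of rows, and the floor adds a wide safety margin; the
test suite checks that doubling the chain length moves SES values by less
than 0.1 on average.

SES = (obs − null mean) / null SD, with the sample (n−1) SD over
replicates; the observed value is never pooled into the null distribution.
Cells with undefined observed metrics or zero null SD get an undefined
SES.  Because the null preserves column sums, any statistic that is a
function of richness alone has zero null SD — the model controls for
richness by construction, and the suite asserts this.  |SES| > 1.96 flags
over-/under-dispersion.  FRic inside null communities reuses the pooled
standardization and PCA basis from the observed data: the null varies
composition, not the trait space.

## Predictors and inference

Last Glacial Maximum climate anomalies are the per-cell mean over the
three general circulation model layers of |current − LGM|.  The
collinearity screen works on the full candidate predictor set in two
deterministic passes: while any pair has |Pearson r| ≥ 0.7, drop from the
worst pair the member with the larger mean absolute correlation to the
remaining variables; then while any variance inflation factor ≥ 5, drop
the largest.  The per-pass drop rule is our construction (only the
thresholds are standard).  The pipeline's regressions use the fixed
eight-predictor set (MAT, AP, both LGM anomalies, cropland, forest and
urban-green-space proportions, elevation SD) rather than the screen's
output, so the design matrix — and in particular the presence of the
predictors the generator injects effects through — does not depend on a
stochastic screen outcome; the screen result is logged in the manifest.

The spatial regression is a statsmodels-style model object:
`ExponentialGLS(y, X, coords).fit()` returns a results object with
estimates, SEs, t and p values, the fitted range, and `summary()`.
Estimation profiles the restricted likelihood (REML default, ML toggle)
over log ρ for the nugget-free exponential correlation
exp(−d/ρ): a 17-point coarse scan over ρ ∈ [10⁻³, 10] × max distance
followed by bounded Brent refinement, with explicit boundary comparison —
the profile is nearly flat when residuals are uncorrelated, where a single
local search can stall at an interior point.  Given ρ, β̂ and σ̂² have
closed forms via the correlation Cholesky factor (a 10⁻¹⁰ diagonal jitter
guards the factorization).  Coefficient p-values use t with n − k df.  The
suite cross-checks estimates, SEs and ρ̂ against `nlme::gls` with
`corExp`.

Dutilleul's modified t-test keeps the Pearson correlation but replaces n
with an effective sample size n̂ estimated from both variables'
distance-class correlograms (Moran-type estimates in 12 equal-width
classes up to half the maximum distance — class construction is
configurable since no standard exists), via
n̂ = 1 + tr(BΣ̂_X)·tr(BΣ̂_Y) / tr(BΣ̂_X B Σ̂_Y) with B the centering
matrix.  With zero estimated autocorrelation n̂ = n and the classical test
is recovered exactly; n̂ is clamped to (2, n].  Simulation shows type-I
error ≈ 0.06 at α = 0.05 on strongly smoothed independent fields where
the naive test rejects ≈ 0.65.

Group contrasts: tie-corrected Kruskal–Wallis H, pairwise Dunn z tests
with Holm adjustment (configurable: none/Bonferroni/Holm), and a
compact-letter display from the maximal cliques of the
not-significantly-different graph.

## The synthetic study system

One root seed drives everything; each component (surfaces, tree, traits,
ranges, suitability) draws from its own child stream keyed by a fixed
component id, so changing one component's draw count cannot perturb the
others.  Defaults define the study conditions at a desk-friendly scale: a 20 × 20
grid of 5-km cells (regional analyses of this kind typically run a few
thousand cells), 30 species, a 0.2 expected trait-incompleteness fraction
(mammal trait compendia commonly lack complete records for roughly a fifth
of a regional fauna), 999 null replicates and ±1.96 thresholds.

* **Surfaces** are seeded white noise smoothed by an isotropic Gaussian
  kernel (`autocorr_length_cells`, default 1.5) and min-max rescaled to
  surface-appropriate ranges — cheap and seedable; the analysis needs
  realistic autocorrelation, not a particular covariance family.
* **Habitat** is the elevation terciles (3 bands), creating realistic
  elevation–habitat confounding.  **LGM layers** are the current surface
  minus a smoothed per-GCM perturbation, so anomaly averaging has
  non-trivial input.  **Land use** is compositional: ten smoothed fields
  normalized to sum to 0.95 per cell.
* **Ranges** are axis-aligned rectangles (keeps intersection exact and
  testable; the assembly accepts general polygons), 0.5–0.95 of the extent
  per side so mean cell occupancy lands near the ~30% typical of regional
  mammal assemblages,
  with centres biased eastward by `richness_gradient_strength` to inject
  the east→west richness gradient.  Elevation tolerances come from pooled
  elevation quantiles; habitat tolerances are random 2–3 band subsets.
* **Traits** are multivariate log-normal with designated pairs correlated
  at `trait_corr` on the log scale; a configurable fraction of species
  gets one missing value.  The **phylogeny** is a forward-simulated
  ultrametric Yule tree.
* **Land-use effects on richness** are injected through a per-species ×
  per-cell Bernoulli suitability mask with keep probability
  logistic(0.5 + 2.0·z_forest − 2.0·z_cropland), applied after
  elevation/habitat refinement.  Rectangles cannot encode a per-cell
  land-use response, so this mask is the generator's ground-truth
  filtering process.  The injected effect is deliberately strong relative to the standardized
  coefficients regional analyses usually estimate: a spatially
  explicit GLS discounts smooth predictors heavily, and at 400 cells a
  weaker effect would not be identifiable — the recoverability the design
  requires (correct signs, p < 0.05, in ≥ 80% of seeded runs at 400
  cells) sets the floor.

What the generator does **not** emulate: real geography or mountain-range
shapes (the six "regions" are grid blocks), real trait covariance beyond
pairwise correlation, range cohesion beyond rectangles, distance decay of
community similarity beyond what range overlap induces, observation error
in range maps, and any climate–trait interaction.  Passing tests therefore
demonstrate that the machinery recovers known structure under the stated
assumptions — not that the real-world estimates of any particular study
are correct.

## Problem sizes in the test suite

The acceptance checks run the chain at reduced but fixed sizes chosen as
the package's own test conditions: 100 random trees for the PD oracle, 50
point sets for the hull oracle, 10⁵ audited trades plus exhaustive
reachability on small matrices for the Curveball chain, 199-replicate SES
calibration over 10 seeds, 100-replicate GLS parameter recovery on a
20 × 20 grid, 500-seed modified-t calibration, and 50 end-to-end runs at
400 cells with 99 null replicates for injected-effect recovery.  The
worked example and end-to-end runs set `fd_max_dim = 4`.

## Known limitations

* FRic at different reduced dimensionalities is not comparable; the
  pipeline fixes one `fd_max_dim` per run and cells below d+1 species are
  undefined rather than back-filled.
* The GLS assumes a nugget-free exponential correlation; no SAR/CAR,
  spatial-eigenvector or model-averaging alternatives are provided, and
  grid-size sensitivity is a configuration option, not an analysis.
* The Curveball sampler is exact for margins but, as with any MCMC
  randomization, uniformity over the fixed-margin set is asymptotic in
  chain length; the defaults are validated by enumeration only on small
  matrices.
* The modified t-test's distance-class correlogram is an estimate; with
  very few cells (< ~100) n̂ is noisy and the test approximate.
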