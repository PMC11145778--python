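# Methods

`phylogrid` implements a complete spatial phylogenetic/functional diversity
workflow for gridded floras: per-cell diversity and structure indices,
range-weighted endemism with CANAPE classification, hotspot and
protection-gap reporting, and environment–driver statistics, together with a
synthetic-data generator that reproduces the statistical structure such
analyses assume. This note records the models, the numerical choices, and
the places where the design was genuinely open.

## Data model

The analysis operates on four aligned objects: a rooted phylogeny with
branch lengths (`Phylogeny`, Newick I/O through dendropy, array-backed
internally); a binary cells × species `OccurrenceMatrix`; a six-trait
`TraitTable` (three continuous: maximum height in cm, maximum leaf size in
cm², flowering-period length in months; three categorical: growth form,
fruit type, flower colour); and a per-cell `CellEnvironment` with eleven
variables in four categories — energy–water (AMT, AP, PDM, PET), climate
seasonality (MDR, TS, PS), human activities (HF) and topography (WA, EVC,
Slope) — plus elevation.

Species are assigned to grid cells when their county set intersects the
cell's counties **and** their closed elevation interval overlaps the cell's
interval; overlap (rather than strict containment) is used because
county-level range data are conventionally rasterised that way. Cells with
less than half their area on land are excluded before assignment. Grid
geometry is abstract (integer row/col); metric projections are out of scope.

Leaf area is estimated as length × breadth × k with k = 2/3 for entire or
dentate leaves, 1/2 for shallow-lobed and 1/3 for deep-lobed leaves;
compound leaves are represented by their largest leaflet by the caller.

## Diversity and structure indices

* **SR** — row sums of the incidence matrix.
* **PD** — Faith's phylogenetic diversity under the *rooted* convention:
  the branch-length sum of the minimal subtree spanning the assemblage
  *including the path to the root*. This matches the common implementations
  (e.g. picante, scikit-bio); unrooted PD differs for small assemblages.
* **MPD** — mean patristic distance over all unordered pairs.
* **NRI** = −1 × (MPD_obs − mean MPD_null) / sd MPD_null, with the null
  drawing k tips uniformly without replacement from the tip pool (the
  "taxa labels" null), k = observed richness. Positive values indicate
  clustering. **FD** and **NFRI** are the same computations on the trait
  dendrogram.

The null is evaluated two ways. The *analytic* scheme (default) is exact:
the null mean of MPD is the grand mean of all pairwise tip distances, and
the null variance has a closed form obtained from the joint inclusion
probabilities of pairs of pairs sharing 2, 1 or 0 tips
(hypergeometric-type coefficients C(n−2,k−2)/C(n,k) etc.). For small
problems (C(n,k) ≤ 1e5) the implementation instead enumerates every
k-subset outright; the two routes agree to machine precision and are tested
against each other. The *montecarlo* scheme draws seeded uniform subsets
(default 999; ≥ 99 required) and uses the sample mean/sd (ddof = 1).
Degenerate nulls (zero variance, e.g. equal-branch star trees) raise an
`UndefinedResult` signal rather than propagating NaN; the assemblage equal
to the whole pool has SES exactly 0. Cells with SR < 2 carry missing
MPD/NRI/NFRI. Closed-form variance smaller than 1e−12 × mean² is clipped to
zero to absorb catastrophic cancellation at k ≈ n.

## Trait space

Gower distance over the six traits: range-normalised absolute differences
for continuous columns, 0/1 mismatch for categorical ones, pairwise-deletion
weights for missing values; a pair with no jointly observed trait is an
error, a zero-range continuous column is dropped with a warning. Traits are
equally weighted. The dendrogram is UPGMA (average linkage) — the
conventional choice after Gower distances — with node heights equal to half
the merge distance, so cophenetic distances reproduce merged distances and
ultrametric inputs are recovered exactly. Ties merge the pair whose
clusters carry the lexicographically smallest descendant labels. An
independent cross-check against scipy's average-linkage cophenetic matrix
is part of the test suite.

## Endemism and CANAPE

* **WE**(c) = Σ 1/range_size over species present in c (an optional range
  threshold restricts the sum; off by default since no defensible value
  exists). Σ_cells WE = number of occurring species exactly.
* **PE**(c) = Σ over spanned branches of length/branch-range-size, where a
  branch's range is the union of its descendants' cells. Σ_cells PE equals
  the occurring subtree's total branch length; on a unit-branch star tree
  PE reduces to WE. **FE** is PE on the trait dendrogram.
* **CANAPE**: PE is computed on the original tree and on a comparison tree
  with identical topology and every branch set equal, scaled to preserve
  total length; RPE is their ratio. The null randomises the incidence
  matrix with curveball trades (every replicate preserves all row and
  column sums exactly; default burn-in 10 × n_cells trades, thinning
  n_cells trades between samples, seeded). Rank p-values use the +1
  correction. A cell is a candidate when either PE tail is significant at
  α = 0.05; candidates are *neo* when RPE is significantly low and *paleo*
  when significantly high (each tail at α/2 = 0.025), otherwise *mixed*;
  mixed cells with both PE tails significant at 0.01 are *super*. Cells
  with zero PE on the comparison tree (empty cells) are non-significant.
  A matrix admitting no trade (e.g. all-ones) yields all p = 1 with a
  warning.

Hotspots are the union of the top-10% cells of endemic SR, WE, PE and FE
(k-th largest cutoff with all ties included, so at least ⌈fraction·n⌉
cells) with all CANAPE-significant cells; protection gaps are hotspot cells
without a protected-area flag.

Because CANAPE decisions are Monte-Carlo, a cell whose p-value sits within
sampling error of a threshold can change class when the replicate count
changes; classifications away from the thresholds are stable (tested
999 vs 4999 replicates).

## Drivers

* **Collinearity screen**: pairs with |Pearson r| strictly above 0.8 are
  flagged; the member not named in the user's keep-list is dropped
  (alphabetically later member when the list is silent); constant columns
  are excluded up front.
* **OLS**: response and predictor z-scored, so the slope is Pearson r and
  R² = r²; two-sided t-test p-values, reported raw (no multiplicity
  correction, matching the tabulated-star convention).
* **Spatial weights**: row-standardised queen contiguity on the lattice
  (rook and Chebyshev distance-band alternatives provided). Eigenvalues of
  the row-standardised matrix are obtained from the similar symmetric
  matrix D^−1/2 A D^−1/2, which is exact for symmetric adjacency.
* **SAR error model** y = Xβ + u, u = λWu + ε, fitted by profile maximum
  likelihood: for fixed λ the spatially filtered regression gives β and σ²,
  log|I − λW| = Σ log(1 − λe_i) from the precomputed eigenvalues, and λ is
  found by bounded Brent search on the feasible interval
  (1/min e, 1/max e). The pseudo-R² is corr(y, Xβ̂ + λ̂W(y − Xβ̂))², stated
  in the fit metadata because no canonical definition exists; coefficient
  p-values are asymptotic normal, conditional on λ̂. Simulation tests
  recover λ = 0.5 within ±0.1 (mean of 200 replicates on a 20 × 20 grid)
  and reduce to OLS when λ = 0.
* **RDA**: columns z-scored; constrained axes are the SVD of the fitted
  values of Y on X, unconstrained axes the SVD of the residuals; axis
  proportions are eigenvalues over the total variance of Y and sum to 1
  across both sets. Aliased predictors are dropped with a warning; each
  axis is signed so its largest-magnitude response loading is positive.
  Verified against vegan's `rda` to 1e−8.
* **Variance partitioning** over the four environment categories: Ezekiel
  adjusted R² (OLS for a univariate response, RDA constrained proportion
  for a matrix response) is computed for all 15 non-empty set unions and
  the 15 exclusive fractions are recovered by solving the
  inclusion–exclusion linear system R(U) = Σ_{T∩U≠∅} e_T. Fractions may be
  negative (retained in output; a display layer may hide them) and sum to
  the full-model adjusted R² by construction. Verified against vegan's
  `varpart` to 1e−6.
* **Jenks natural breaks**: exact Fisher–Jenks dynamic programming over
  sorted values (O(k·n²)); ties spanning a break fall in the lower class;
  verified against exhaustive search for n ≤ 12, k ≤ 4. Default ten
  classes.
* **Elevational gradients**: standardised single-variable OLS of each index
  on cell elevation. A GAM for the hump-shaped NRI–elevation relationship
  is deliberately not implemented; the linear fit is a descriptive
  summary only.

## Synthetic data generator

The generator provides the study conditions for every downstream test. All
generators are pure functions of (config, seed); `simulate_dataset` derives
sub-seeds from one master seed via `SeedSequence`.

* **Phylogeny**: Gillespie birth–death (default birth 1.0, death 0.0)
  conditioned on the extant tip count, restarting on total extinction. The
  simulation stops when the count first reaches n and extends all tip edges
  by an Exp(n(b+d)) stem, so terminal branches are strictly positive (a
  tree truncated exactly at the n-th speciation has zero-length tips, which
  degenerates pairwise distances). Extinct lineages are pruned and
  unifurcations spliced; trees are ultrametric by construction.
* **Traits**: the three continuous traits evolve as Brownian motion with a
  shared common factor (loading √0.8 — the plant size syndrome: tall
  species have larger leaves and longer flowering periods), mapped to
  positive scales by exponentiation/offset. The three categorical traits
  use a Brownian threshold (liability) model: a latent Brownian trait cut
  at empirical quantiles sized by the configured class frequencies (growth
  form 90% hygrophyte / 10% aquatic classes, mirroring the strong
  hygrophyte dominance of alpine wetland floras). Close relatives
  therefore share classes — growth form and fruit type are strongly
  conserved in real floras — while marginal frequencies match the
  configuration exactly. At Brownian rate 0 all continuous traits are
  constant and categorical classes fall back to iid draws.
* **Landscape**: an n_rows × n_cols grid (default 10 × 10) with a linear
  climate gradient along the SE→NW diagonal: temperature, precipitation,
  human footprint and relief decline toward the NW while PET and the
  seasonality variables rise; elevation runs opposite to temperature
  (default 4000 ± 1200 m, noise sd 100 m). Each cell carries its own
  county, a protected flag (Bernoulli 0.3) and a 400 m within-cell relief.
* **Communities**: each species draws a range size from lognormal(μ = 2,
  σ = 1) cells (right-skewed, clipped to [1, n_cells]; with the default
  endemic threshold of 3 cells about a fifth of species are endemic,
  matching the endemic fraction typical of such floras). Its niche optimum
  on the standardised temperature axis is 0.8 + 0.6 × (standardised
  phenotype), one optimum per continuous trait; the +0.8 bias places more
  optima toward the warm/wet corner, so richness declines with elevation
  as energy–water-limited floras do. The range seed cell and every growth
  candidate are sampled ∝ exp(−φ·mismatch²) with mismatch averaged over
  the three phenotype dimensions, and a sampled candidate establishes with
  the same probability relative to the species' best cell — so at large φ
  realised ranges truncate inside matched terrain instead of overflowing
  the drawn size. φ = 0 reduces to environment-blind contiguous ranges.

With these defaults the generator reproduces, and the tests verify, the
causal chain the analysis is meant to detect: φ = 0 gives median NRI and
NFRI near zero; φ = 5 gives clearly positive medians of both (filtering on
Brownian phenotypes clusters relatives, and the liability-model categorical
traits carry that signal into the Gower dendrogram); strong filtering
compresses within-cell phenotype variance below the landscape-wide variance
in essentially all cells.

What the generator does **not** emulate: real geography (ranges are
abstract lattice blobs, no dispersal barriers or riverine structure),
speciation–extinction dynamics coupled to the landscape, abundance
(incidence only), sampling effort artefacts, spatially autocorrelated
residual richness beyond what contiguous ranges induce, and collinearity
structure among environment variables beyond the shared gradient. Passing
tests therefore demonstrate the *machinery* is correct and the
filtering→clustering logic detectable under controlled conditions — not
that any particular empirical flora will show those effects.

## Problem sizes

Default test and acceptance scale: 10 × 10 grid, 64 species — large enough
for stable nulls and spatial fits, small enough that exhaustive oracles
(subset enumeration, brute-force Jenks, 999–9999-replicate randomisations,
200-replicate SAR recovery) run in seconds to a few minutes.

## Known limitations

* NTI/MNTD, abundance-weighted metrics and phylogenetic beta diversity are
  out of scope.
* The SAR fit profiles λ by concentrated likelihood; standard errors for β
  are conditional on λ̂ (no information-matrix correction for λ
  uncertainty).
* The CANAPE null preserves both cell richness and species range sizes
  (curveball); other null choices (richness-only) would give different
  p-values and are not implemented.
* Checklist parsing merges infraspecific taxa by truncating to the
  binomial; it does not standardise names against a taxonomic backbone.
* Single-threaded throughout; the largest intended problems (a few
  thousand cells × a few thousand species) are well within reach, but the
  O(n³) UPGMA and dense patristic matrices make ~10⁴ species impractical.
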