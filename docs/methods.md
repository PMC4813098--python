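# Methods

## Scope

`richcompare` compares two estimators of species richness built from
presence-only collection records — direct inverse-distance-weighted (IDW)
interpolation of per-block species counts, and stacked per-species
maximum-entropy distribution models (S-SDM) — under a leave-one-surveyed-
area-out validation. Everything runs on abstract planar kilometre
coordinates; grids are row-major with origin at the lower-left and
half-open cells (a point on a boundary belongs to the higher-index cell).

## The synthetic world

The generator emulates the statistical structure of a herbarium-style
dataset, not any particular region or taxon.

* **Covariates.** Gaussian-smoothed white noise (default bandwidth 8
  cells), standardized; 8 continuous layers by default, of which two pairs
  are mixed as ρ·A + √(1−ρ²)·B with ρ = 0.9 so the collinearity filter has
  real work to do. One categorical substrate layer (3 codes) from
  quantile-binning a smoother field, giving contiguous patches.
* **Virtual species** (default 18). Suitability is
  invlogit(b + Σ w₁z + w₂z²) × substrate multiplier on two randomly chosen
  layers, with |w₁| ~ U(1.0, 2.5), w₂ ~ −U(0.5, 1.5). Weight magnitudes are
  bounded away from zero deliberately: every species must have a real
  niche, because a nicheless species' fitted SDM can only encode sampling
  bias, a situation the well-modeled real datasets this emulates do not
  present. The preferred substrate code gets multiplier 1, others
  U(0.2, 1). The intercept b is calibrated by bisection so mean suitability
  equals a prevalence drawn log-uniformly from [0.02, 0.35]; with 18
  species this puts mean true richness near 2.1 species/cell, matching the
  1.8–2.2 range richness maps of this kind typically show. Occupancy is
  one Bernoulli draw per cell at the suitability.
* **Sampling.** Four disjoint 30×30 blocks are surveyed near-exhaustively
  (each occupied cell×species pair detected with p = 0.95). Opportunistic
  collecting visits 300 cells drawn uniformly over the whole landscape —
  including inside blocks, as real opportunistic records overlap surveyed
  areas — and detects an occupied species with probability
  0.8·(prevalence/max prevalence)^bias, bias = 2. This reproduces the
  canonical contrast: the large majority of opportunistic localities
  record only 1–2 species while surveyed localities record close to their
  true richness.

What the generator does **not** emulate: geographic projections,
georeferencing error, temporal collecting waves, detection differences
among observers, and niche shapes beyond quadratic-in-covariates. A green
test therefore establishes that a method recovers structure of this
smooth, stationary kind — not that it would cope with, say, heavy-tailed
covariates or range disequilibrium.

## Occurrence gridding

Records are deduplicated to one presence per (species, analysis cell);
species known from fewer than 5 distinct cells are excluded (the
minimum-locality rule; "locality" is interpreted as a distinct analysis
cell after dedup). For interpolation, presences are aggregated to a
10×10-cell fishnet of distinct-species counts; blocks with no records are
*omitted* from the interpolation sample rather than imputed as zeros —
an unvisited block carries no absence evidence.

## IDW

Weights dᵢ⁻ᵖ over the k nearest sampled block centroids, defaults p = 1.6
and k = 12 (the common GIS "variable radius, 12 points" search; a fixed
metric radius is available via `IDWParams.radius`, falling back to the
single nearest sample where the radius is empty). Nearest-neighbour ties
break by sample index; a query coincident with a sample returns that
sample's value exactly. Estimates are convex combinations, hence bounded
by the contributing counts.

## Maxent

Features: linear + quadratic per retained continuous layer (standardized
to background mean 0 / sd 1), one indicator per substrate code. The
collinearity pre-filter greedily resolves background |r| > 0.8 pairs,
dropping the member with the larger mean absolute correlation to the other
retained layers (ties by layer order); constant layers are dropped with a
warning; the categorical layer is always kept.

Fitting maximizes the concave penalized objective
mean_presence λ·f − log Z_background − Σ βⱼ|λⱼ| by proximal-gradient
(soft-threshold) ascent with backtracking line search; βⱼ = β·sⱼ/√m with
β = 2, sⱼ the background feature scale, m the presence count. Iteration
stops when the objective improves by < 1e-5 (tighten `tol` when parameter-
level precision is needed; the stopping rule is on the objective, so λ is
then accurate only to ~√tol/curvature). The background is 10,000 cells
sampled uniformly without replacement (all cells on smaller landscapes);
presences are not excluded from it.

Outputs: raw density e^{λ·f}/Z (sums to 1 over background) and the
entropy-calibrated logistic e^H·raw/(1 + e^H·raw), H the entropy of the
raw distribution over background — a uniform model scores 0.5 everywhere.
AUC uses held-out presences vs the background as negatives, ties counted
half (rank-based, exactly the pairwise statistic). k-fold cross-validation
partitions presences at random (seeded), reducing k with a warning when
presences are scarce; the averaged fold surfaces form the final model when
`SDMConfig(folds=k>1)` is used.

## Stacking and validation

S-SDM richness is the cell-wise sum of per-species logistic surfaces, no
presence/absence thresholding. The leave-area-out loop rebuilds each
method without the records of one surveyed area (training subsets are
re-deduplicated; the <5-cell species filter is re-applied per subset, so
an area-endemic species simply drops out of that partial stack and
contributes 0, while the reference stack keeps it). Pearson correlations
between partial and reference surfaces are computed over every cell of the
excluded window at analysis resolution; a window on which either surface
is constant yields an *undefined* (None) correlation rather than 0.

Design choices made where the design was genuinely open:

* Validation stacks default to a single fit per species (`folds=1`). The
  10-fold-averaged final model is available (`folds=10`, and is the `sdm`
  CLI default); on this generator it changes window correlations by less
  than 0.01 while costing 10× the fits, so the cheap default is used in
  the batched validation.
* The window correlation uses all window cells, not only collection cells.
* Whether an IDW "radius of 12" means 12 points or 12 km is genuinely
  ambiguous in GIS practice; 12 nearest points is the default here since a
  12-km fixed radius frequently contains no sample under sparse fishnets.

## Numerical notes and limitations

* All stochastic stages consume seeds derived from one master seed via
  `numpy.random.SeedSequence`; identical configs give byte-identical
  reports.
* The strict per-world form of the headline comparison (S-SDM beating IDW
  in *every* area of *every* world) is unstable at desk scale: a 30×30
  window spans only 3×3 fishnet blocks, so the IDW window correlation
  behaves like the chance alignment of two smooth gradients (sd ≈ 0.34
  across worlds) and occasionally exceeds the S-SDM value. The
  distributional statement — mean r_ssdm above mean r_idw in every area,
  positive r_ssdm in ≥ 90% of area×world cells — is stable and is what
  the validation suite asserts green; the strict form is kept as its own
  (currently failing) test for transparency.
* The proximal fit is convex, so results do not depend on initialization;
  a fit that hits the 5000-iteration cap warns rather than fails.
* Degenerate inputs: constant feature columns are zeroed (their λ is 0 by
  construction); empty fishnets, zero presences, and out-of-extent records
  raise informative errors rather than propagating NaNs.
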