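# richcompare

Mapping species richness from natural-history-collection records, two ways,
and measuring which way generalizes.

## The problem

For inconspicuous taxa (bryophytes, invertebrates), most of what we know
about distributions sits in museum and herbarium collections: presence-only
records, collected opportunistically, heavily biased toward accessible
places and conspicuous or common species. Conservation planning has
traditionally turned such records into richness maps by direct spatial
interpolation — count the species per grid cell, interpolate the counts.
The alternative is to fit one presence/background species distribution
model (SDM) per species against environmental covariates and sum the
per-species suitability surfaces into a *stacked SDM* (S-SDM) map of
potential richness.

`richcompare` implements both estimators and the validation that separates
them: leave out all records from one well-surveyed area, rebuild each map,
and correlate the rebuilt ("partial") map against the all-data
("reference") map inside the left-out window. Because real collection data
of this kind are rarely shareable, the package includes a synthetic world
generator — spatially autocorrelated covariates, virtual species with
known niches, and a two-regime sampling process (exhaustive blocks +
commonness-biased opportunistic collecting) — so the whole pipeline is
testable end to end with known truth.

## The methods

**IDW richness.** Distinct species per 10×10-cell fishnet block;
interpolation onto the analysis grid by inverse distance weighting over the
k = 12 nearest sampled block centroids with weights d⁻¹·⁶:

  ẑ(q) = Σᵢ dᵢ⁻ᵖ zᵢ / Σᵢ dᵢ⁻ᵖ

**Stacked maxent SDMs.** Per species, an L1-regularized log-linear density
over a 10,000-cell background sample, maximizing

  J(λ) = mean₍presence₎ λ·f(x) − log Σ₍background₎ e^{λ·f(x)} − Σⱼ βⱼ|λⱼ|

with linear + quadratic features per covariate (collinearity-filtered at
|r| > 0.8) plus categorical substrate indicators, βⱼ = β·sⱼ/√m with β = 2.
Raw densities are mapped to suitability by the entropy-calibrated logistic
transform e^H·raw/(1 + e^H·raw) and summed over species without
thresholding. Model quality is reported as k-fold cross-validated AUC with
background points as negatives (ties counted half).

## Worked example

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

prints (seed 1):

```
seed 1: 6370 occurrence records
  area1: r_idw=+0.2116  r_ssdm=+0.8983  (excluded 1865 presences)
  area2: r_idw=-0.5770  r_ssdm=+0.8323  (excluded 1393 presences)
  area3: r_idw=-0.3599  r_ssdm=+0.6359  (excluded 1205 presences)
  area4: r_idw=-0.2581  r_ssdm=+0.5591  (excluded 1718 presences)
  cross-method r = +0.3283
```

Each row is one leave-area-out experiment: the Pearson correlation, inside
the excluded 30×30 km window, between the reference map and the partial map
rebuilt without that area's systematic records. The stacked SDM keeps
predicting the window's richness pattern from the species' environmental
responses learned elsewhere (r ≈ 0.56–0.90); the interpolated map cannot —
with the window's data gone it extrapolates the sparse, species-poor
opportunistic counts around it (r ≈ −0.58…+0.21). The footer is the
full-extent correlation between the two reference maps, showing the two
approaches describe richness quite differently even with all data in hand.
The script recomputes everything from scratch at the given seed and writes
the (empty) results JSON for downstream tooling.

The same pipeline is scriptable from the shell:

```
richcompare simulate --seed 1 -o world/
richcompare idw --records world/records.csv --layers world/layers -o idw.asc
richcompare sdm --presences world/records.csv --layers world/layers \
    --species sp03 --folds 10 --seed 1 -o sp03.asc
richcompare validate --seed 1 -o report/
```

See `docs/methods.md` for the model assumptions, parameter defaults, and
what the synthetic world does and does not emulate.
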