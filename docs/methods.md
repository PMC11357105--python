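# Methods

`trianiche` tests the macroecological niche breadth–range size hypothesis
in Triatominae (kissing bugs, vectors of Chagas disease): do species that
tolerate a wider span of climatic conditions, or feed on a wider array of
hosts, occupy larger geographic ranges? This note describes the models,
the measurement definitions, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Measurements

**Range size.** A species' range is an alpha shape over its cleaned
occurrence points: the union of Delaunay triangles (in lon/lat degrees)
whose circumradius is at most α. The dynamic variant starts at
α = 3° and grows it in 1° increments until the hull has at most
`max_parts` (default 1) connected components and contains at least
`fraction` (default 0.95) of the occurrences; the convex hull satisfies
both, so termination is guaranteed. These defaults are explicit,
configurable stand-ins — range polygons fitted this way are not very
sensitive to them, but the chosen α is always reported per species.
Area is computed on a sphere of authalic radius R = 6371.0088 km by the
spherical-excess (Gauss–Bonnet turn-angle) formula with geodesic edges,
holes subtracted and multipart hulls summed. Deviation from ellipsoidal
(WGS84) area is below ~0.3%, far inside hull uncertainty. Rings larger
than a hemisphere are out of scope (the smaller complementary area is
reported). Triangulation happens in raw degrees; point sets spanning
more than 90° of longitude trigger a warning because degree-space
circumradii are then distorted and the antimeridian is not unwrapped.
Hulls are not clipped to coastlines; a user-supplied land mask can be
intersected downstream if desired. Species with fewer than 3 unique
non-collinear points are excluded with a logged reason.

**Climatic niche breadth.** From four bioclim layers at each occurrence
cell (containing-cell lookup, no interpolation; membership is half-open,
[west, east) × (south, north], so edge points land in exactly one cell):

* TNB (°C) = max(bio5) − min(bio6): warmest-month maximum minus
  coldest-month minimum over the species' cells — the annual thermal
  envelope the species spans;
* PNB (mm) = max(bio16) − min(bio17): wettest-quarter maximum minus
  driest-quarter minimum precipitation.

Both are non-negative whenever the rasters satisfy the cellwise sanity
conditions bio5 ≥ bio6 and bio16 ≥ bio17; violations are treated as
corrupt input, not silently clipped. Raster I/O supports the ESRI ASCII
grid format (plain text, trivially diffable); grids must share one
extent and resolution.

**Diet breadth (DBR).** The number of distinct host taxa detected in a
species' blood meals, at each of five nested ranks (class, order,
family, genus, species). Hosts resolved below a rank collapse to their
ancestor; hosts unresolved *at* a rank are excluded from that rank's
count (logged) — the alternative of counting each unresolved parent as
one unit is available behind `include_unresolved=True` but inflates
counts at fine ranks and is not the default. Feeding profiles allocate
mixed-meal individuals across their component host categories in
proportion to those categories' pure-meal counts (equal split when no
component has pure meals); allocation conserves the individual count to
1e−9.

**Occurrence cleaning.** Records are dropped, in order, for missing or
unparseable coordinates, exact (species, lon, lat) duplicates (no
coordinate rounding), and falling outside the study region — by default
an Americas bounding box, lon ∈ [−170, −25], lat ∈ [−60, 75],
overridable by any polygon. No automated outlier detection is applied:
"potentially misidentified" is operationalized purely as out-of-region.
Cleaning is idempotent and every drop is counted per species per reason.

## Phylogenetic signal

Under Brownian motion on a rooted, dated tree, tip trait values are
jointly Gaussian with covariance σ²C, where C[i,j] is the depth of the
most recent common ancestor of tips i and j (root-to-tip distance on
the diagonal). Pagel's λ multiplies the off-diagonals of C; λ = 1 is
Brownian motion, λ = 0 phylogenetic independence. λ is restricted to
[0, 1] (not the wider range some software allows) to match its
interpretation as an index.

* **Blomberg's K** = (MSE₀/MSE)_obs / (MSE₀/MSE)_BM, where the mean is
  the phylogenetic GLS mean â = (1ᵀC⁻¹x)/(1ᵀC⁻¹1), MSE₀ the ordinary
  mean squared deviation from â, MSE the C-weighted one, and the
  Brownian expectation is [tr(C) − n/(1ᵀC⁻¹1)]/(n−1). K is invariant to
  affine trait rescaling and equals 1 exactly on a star phylogeny.
* **Pagel's λ̂** maximizes the profile log-likelihood
  ℓ(λ) = −½[n ln(2πσ̂²(λ)) + ln|C(λ)| + n] with μ and σ² profiled out,
  by bounded Brent search (tolerance 1e−8) plus exact evaluation of
  both endpoints; near-ties break toward the smaller λ. A flat profile
  (star tree) is reported as λ̂ = 0 with a non-identifiability flag
  rather than an arbitrary interior value.
* **P-values** use tip-label permutation with the add-one estimator
  p = (1 + #{stat_perm ≥ stat_obs})/(1 + n_sims), never exactly zero,
  seeded and bit-reproducible. This reproduces the characteristic
  λ̂ = 0 → p = 1 pattern of signal-free data. A parametric
  likelihood-ratio p for λ (χ²₁ against λ = 0) is provided as an
  alternative, not the default. Permutation ties are counted with a
  hair of floating-point tolerance so exchangeable nulls (star trees)
  give p = 1 instead of splitting on rounding noise.

Topological uncertainty is propagated by recomputing each statistic on
every tree of a topology set and reporting the median with a 2.5–97.5
percentile interval (linear-interpolation quantiles). The permutation
stream is shared across topologies (per trait × index), so duplicated
topologies give identical summaries. Per-topology failures are logged
and excluded, never silent. Species missing a trait are handled by
restriction of C (equivalent to pruning). Singular covariances (e.g.
zero-length cherries in posterior topologies) raise an explicit error
rather than being regularized.

## The regression

ln(area_km2) ~ ln(DBR) + √TNB + √PNB, fit by OLS and by PGLS with
residual covariance σ²C(λ), λ estimated by ML on [0, 1] (same Brent
scheme). Natural logs are used (slope tests are base-invariant).
Standard errors use the unbiased residual variance RSS/(n−p), so PGLS
with λ = 0 on an ultrametric tree reproduces OLS exactly — a tested
identity. PGLS R² is the generalized 1 − RSS/TSS against the GLS
intercept-only baseline. Before fitting, pairwise Pearson correlations
between the transformed predictors are reported and |r| ≥ 0.4 flagged
(warning only). The model is replicated over the five DBR ranks and
over overlapping habitat strata (domiciliary, peridomiciliary,
sylvatic — a species contributes to every habitat it uses, plus the
all-species stratum; habitat is never a predictor). OLS is
topology-independent and fit once; PGLS is repeated per topology and
summarized as medians with 95% percentile intervals. No
multiple-testing correction is applied across ranks × strata. Strata
with fewer than 5 complete species are skipped with a logged reason.

## Synthetic data

The generators make the full pipeline testable without downloads, and
their defaults define the conditions under which the test suite's
statistical guarantees are verified:

* **Trees**: pure-birth (Yule) trees, crown-to-present simulation with
  Exp(k·birth_rate) waiting times at k lineages and a final stretch at
  n lineages, hence ultrametric with expected root height
  Σ_{k=2..n} 1/(k·b).
* **Traits**: draws from MVN(μ1, σ²C(λ)) via Cholesky, λ tunable.
* **Regression datasets**: the model inverted — DBR as 1 + Poisson
  (mean 6 at species rank, coarser ranks shrunk deterministically),
  TNB log-normal around ~25 °C, PNB log-normal around ~1100 mm, so the
  log/√ transforms are exercised on realistic scales; residuals
  MVN(0, σ²C(λ_resid)). Habitat flags follow the overlapping
  composition observed in the real assemblage (60% in all three
  habitats, 16% domiciliary+peridomiciliary, 12% sylvatic-only, …).
* **Landscapes**: Gaussian occurrence clusters inside the Americas box
  over rasters with a latitudinal gradient (bio5 declining with |lat|,
  bio6 = bio5 − positive offset, bio16 ≥ bio17 by construction — a hard
  guarantee, asserted), plus injected duplicates, out-of-region and
  missing-coordinate records to exercise cleaning.
* **Blood meals**: individuals feed on one host (prob 1 − mixing_prob)
  or two distinct hosts, over a small nested host taxonomy of typical
  triatomine blood sources (including one host resolved only to family,
  to exercise the unresolved-rank rule); ground-truth DBR at all ranks
  is returned for validation.

One global seed expands to per-component substreams through fixed
component keys, so adding a generator never shifts existing streams.

What the generators do **not** emulate: spatial sampling bias and
coordinate error in GBIF records, coastline-constrained ranges, niche
conservatism beyond the λ mechanism, host-availability structure in
diets, and non-ultrametric or calibrated-node trees. Passing tests
therefore demonstrate that the estimators are correct and calibrated
under their stated models, not that any particular empirical dataset
satisfies those models.

## Calibration study sizes

The statistical test suite verifies: K = 1 to 1e−10 on star trees;
mean K over 1,000 Brownian simulations on a 50-tip tree inside
[0.9, 1.1]; mean λ̂ within ±0.1 of λ_true ∈ {0, 0.5, 1} at 200 tips
(100 replicates each); permutation type-I error inside [0.03, 0.07]
over 1,000 signal-free datasets (500 permutations each, Blomberg's K on
a 50-tip tree); PGLS(λ=0) ≡ OLS to 1e−8 on 20 designs; and, for the
regression with β = (1, 0, 0.5, 0.3), λ_resid = 0.7, σ²_resid = 0.25 on
100-tip trees over 200 replicates: componentwise mean β̂ within ±0.1,
95% CI coverage within [0.90, 0.98], the √TNB slope rejected in ≥ 80%
of replicates and the null ln(DBR) slope in ≤ 10% — the qualitative
pattern the hypothesis test is meant to resolve (climate slopes
detectable, diet slope null). σ²_resid = 0.25 was fixed by an a-priori
power calculation: the √TNB effect (sd ≈ 0.43 across species) against a
whitened residual sd ≈ 1 at the Yule tree height (~4.2) yields t ≈ 4
and power > 0.9 at n = 100, a regime where detection is expected rather
than marginal. `scripts/acceptance.py` recomputes slightly scaled-down
versions of these quantities plus a full end-to-end pipeline run
(30 species, 10 topologies, 200 permutations).

## Known limitations

* Degree-space triangulation distorts east–west distances at high
  latitude; for high-latitude or antimeridian-spanning taxa a projected
  workflow would be needed (the Triatominae use case is tropical to
  mid-latitude).
* The λ permutation p-value refits λ̂ for every permutation, which is
  O(n³) per permutation; for very large trees the likelihood-ratio p is
  the cheaper alternative.
* PGLS standard errors condition on λ̂ (as is conventional); the
  topology-ensemble intervals capture tree uncertainty but not λ
  estimation uncertainty within a topology.
* The cross-topology 95% intervals are percentile intervals and are
  labelled as such.
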