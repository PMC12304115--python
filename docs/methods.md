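# Methods

This note documents the model, the synthetic data that the tests run on,
the numerical choices, and the known limitations of `fishdiv`.

## Model and assumptions

Richness at M river sites is modelled as

B ~ N(μ(θ), σ²I),  μ(θ) = a + b·ln Q + C(r)·V,  θ = (r, a, b, V),

with Q the long-term mean discharge (m³/s) and C(r) the M×K matrix of
decay-integrated land-cover exposures

c_ik = (3/r) Σ_{j: LULC_j = k} A_j exp(−3 d_ij / r),

summed over the pixels of site i's flow-routed catchment (d_ij = flow
distance in km, A_j = haversine pixel area in km²). The exponential
kernel f(d) = (3/r)e^(−3d/r) is a unit-integral density whose value at
d = r is e⁻³ ≈ 5% of its peak, so r reads directly as the effective
upstream range of terrestrial influence. Assumptions: i.i.d. Gaussian
errors (no spatial error correlation), one shared r across cover classes,
effects additive in decay-weighted area, and no climate covariates (the
intended setting is a thermally homogeneous basin; for basins spanning
biomes a temperature term would belong in the baseline). Water and other
excluded covers carry class 0: they route flow but contribute no
exposure. For count-flavoured analyses a Poisson or negative-binomial
likelihood with log link is available (`fit_count_model`), fitted by
numerical optimization; the Gaussian model is primary.

Species-level occurrence uses the same linear predictor on the logit
scale. A Gaussian error on the logit of a 0/1 observation is not directly
fittable, so the species model is estimated as a Bernoulli GLM — ridge-
stabilized logistic regression (λ = 1e-4 on b and V, never on the
intercept) with r profiled per species on a grid. Species present or
absent at fewer than 3 sites are flagged non-fittable. Each species'
land-cover association is argmax_k V_k (ties flagged, lowest index), and
presence maps are binarized at the threshold maximizing the true skill
statistic (sensitivity + specificity − 1), lowest threshold among ties.

## Estimation and inference

- **Profile likelihood in r.** For fixed r the Gaussian MLE of (a, b, V)
  is OLS on [1, ln Q, C(r)] and σ̂² = RSS/M (MLE divisor). r is maximized
  over a log-spaced grid (default 60 points on [1, 500] km) followed by
  bounded Brent refinement (xatol 1e-8 km). The profile can be
  multi-modal, hence grid-first; exact ties resolve to the smallest r
  (parsimony of spatial range). Classes absent from every catchment are
  dropped from the design with a warning, their effect fixed at 0.
- **Confidence intervals.** Profile likelihood-ratio intervals with the
  exact Gaussian small-sample calibration: the set of values where
  (RSS_v − RSS_min)/(RSS_min/(M−p)) ≤ F(1, M−p), p counting all mean
  parameters including r. This equals the χ²₁ rule asymptotically but has
  materially better coverage at M ≈ 40 (χ²₁ undercovers by ~6 points
  there). For r the profile is scanned on a fine grid for the outermost
  crossings (robust to multi-modality) and each edge sharpened by
  bisection; for linear coefficients the profile re-optimizes all other
  parameters including r at each fixed value. Simulated 90% intervals for
  r cover the truth at ~86–89% under the default study conditions — the
  residual shortfall is the usual nonlinear-parameter approximation.
- **Per-effect tests.** Each V_k (and b) is tested by a likelihood-ratio
  comparison of full vs reduced design, both evaluated at the r profiled
  under the *reduced* model, calibrated by F(1, M−p). The nuisance r must
  be estimated without reference to the tested column: letting each model
  profile its own r, or fixing r at the full-model estimate, selects the
  design that most flatters the tested effect and inflates the 5%-level
  rejection rate to ~0.2–0.4 under the null, while the reduced-model-r
  variant is calibrated (0.02–0.06 in 200-simulation checks). The
  significance of r itself is reported as the full model against the
  no-LULC model with df = 1 and an explicit caveat: r is undefined under
  that null (boundary problem), so this p-value is approximate.
- **Adjusted R².** 1 − (1−R²)(M−1)/(M−p−1) with p = K + 2 mean-structure
  parameters beyond the intercept (b, the K effects, and r). Whether r
  should count is arguable; `count_r_in_p=False` switches to K + 1.
- **Validation.** Leave-one-out CV refits everything (including r) per
  fold and reports RMSE; failed folds are flagged and excluded with a
  warning. The site-resampling bootstrap (default 2000 draws) redraws
  degenerate (constant-richness) resamples up to 10 times. Collinearity
  diagnostics report VIF_k = 1/(1−R²_k) per design column and the Pearson
  correlation matrix at the fitted r; region-split refits rerun the whole
  estimation on site subsets.

## Effect maps and projection

The terrestrial effect of pixel j on riverine richness per km of river is
the closed form of integrating the kernel along the in-river section of
j's flow path: E_j = V_k(j)·e^(−3L_ter/r)·(1 − e^(−3L_riv/r)), where
L_ter is the terrestrial path length from j to the first major-channel
pixel and L_riv continues downstream until L_ter + L_riv reaches r
(inclusive truncation; pixels that never reach a channel within r get
E = 0). Path lengths accumulate pixel-center haversine steps, diagonals
included. Channel richness projection computes μ at every major-channel
pixel; by default it uses the pixel's full upstream catchment so that a
training site's projection equals its fitted value exactly, and the
field-practice truncation at flow distance r is available via
`max_distance=r` (its error is bounded by |V|_max·(3/r)·ΣA·e⁻³, verified
in tests). Scenario deltas are 100·(new − old)/old per channel pixel,
undefined where old = 0. Jaccard similarity of two predicted assemblages
uses |A∩B|/|A∪B| with the empty-vs-empty case defined as 1 (identical
communities) — a convention, noted here because both conventions appear
in the literature.

## Neutral meta-community null model

The null model is an intentionally simple neutral surrogate, not a
reimplementation of any published metacommunity simulator. Channel pixels
are grouped into reaches (≤ reach_length pixels, cut at confluences);
reach i holds a fixed community of J_i = max(1, round(c·ln(1+Q_i)))
individuals. Each generation every individual is replaced by a new
species with probability ν, by an immigrant from a uniformly chosen
adjacent reach with probability m(1−ν), else by a local parent —
synchronous zero-sum Moran dynamics from a monodominant start. Richness
gradients can therefore arise only from capacity, drift, dispersal, and
network structure. Calibration is uniform random search (ν log-uniform on
[1e-4, 0.1], m uniform on [0, 1], c log-uniform on [2, 60] by default,
ranges configurable), scoring candidates by the adjusted R² of a linear
calibration regression of observed site richness on simulated reach
richness. Burn-in defaults to 50× the largest J_i; the desk-scale
comparisons in the test suite use 400 generations, 30 candidates, and
c ≤ 15, which suffices for the null-comparison role. Climate is omitted
(the synthetic world is thermally homogeneous).

## The synthetic landscape generator

The generator defines the study conditions under which every stochastic
guarantee in the test suite is stated.

- **Flow network**: a random spanning tree of the grid rooted at a random
  border outlet, built as the shortest-path tree under log-normal
  randomized edge costs (`tortuosity`, default 1.0). A uniformly random
  spanning tree is *not* used deliberately: its space-filling paths give
  flow distances many times the Euclidean separation, unlike any real
  drainage network, and distance-decay exposures computed on such paths
  are unrecognizably distorted.
- **Scale**: 120×120 pixels at a nominal 2 km cell (~240 km basin,
  subtropical latitude). The domain must dwarf the ~19 km effective
  distance for the spatial range to be identifiable — with these defaults
  flow distances reach 150–300 km and the decay-weighted land-cover
  signal has SD ≈ 9 species against residual σ = 5, the magnitude
  relation a large-basin survey of this kind exhibits (site richness
  SD ≈ 10, residual SD ≈ 5–6).
- **Land cover**: Gaussian white noise smoothed at `autocorr_scale`
  (default 8 px ≈ 16 km patches, the scale of a forest-mountain vs
  cropland-plain mosaic), rank-transformed to uniform and cut at the
  cumulative class weights — marginal covers match the weights exactly,
  by construction. Default covers 44/12/36/7/1% (rainfed cropland,
  irrigated cropland, forest, shrub-/grassland, urban).
- **Discharge**: Q = 0.01 m³/s per km² of accumulated drainage area —
  monotone downstream by construction. Major channels: accumulation ≥ 15
  pixels (≈ 60 km²). Sites: uniform over channel pixels subject to a
  minimum inter-site *flow* distance (10 pixels); sites on separate
  tributaries do not constrain each other.
- **Observations**: B_i drawn from the Gaussian model at recorded true
  parameters (TruthRecord is never mutated by fitting). Richness is
  real-valued by default, matching the Gaussian model; integer rounding
  is available because observed richness is a count, and the package
  takes no position on which a given survey "really" is.

What the generator does *not* emulate: real geography (elevation,
climate gradients), anisotropic or discharge-dependent kernel shapes,
eDNA transport and detection error, spatially correlated residuals, and
channel-position uncertainty. Passing tests therefore demonstrate that
the estimation machinery is correct and calibrated under the model's own
assumptions — not that the model is adequate for any particular river.

A known small-sample feature of the study conditions: the 1%-cover urban
class is exposed in only 1–4 of the 40 site catchments per realization.
An effect supported by a single site is unidentifiable under
leave-one-out, so noise-free LOOCV identities are asserted on landscapes
where every class has support at ≥ 3 sites (checked up front, before any
fitting).

## Numerical choices and degenerate inputs

- Earth radius fixed at 6371 km; all distances and areas by haversine on
  pixel centers (diagonal steps use the true diagonal center distance).
- D8 codes follow the ESRI power-of-two convention (1 = E … 128 = NE),
  0 = outlet, 255 = nodata; pixels whose successor leaves the grid drain
  to an external outlet and join no catchment. Cycles are detected during
  accumulation and reported with a pixel coordinate.
- σ̂² is floored at 1e-300 inside log-likelihoods so that noise-free fits
  (RSS → 0) remain finite and comparable.
- Rank-deficient designs: all-zero exposure columns are dropped with a
  warning; remaining degeneracy falls through to `lstsq` (minimum-norm).
- TSS threshold candidates are the unique predicted probabilities;
  prediction is p ≥ threshold; ties resolve to the lowest threshold.
- Kernel plugins (half-normal, linear-taper, uniform-window,
  inverse-power) are normalized to unit integral and parameterized so the
  density at d = r is ≤ ~5% of its peak; they are labelled alternatives
  for sensitivity analysis, not claimed equivalents of any particular
  published comparison set.
- Desk-scale problem sizes used by the test suite: 120×120 landscapes
  with 40 sites for recovery/calibration/coverage (50, 200, and 200
  replicates), 60×60 with 12 sites for unit tests, 30×30 for brute-force
  oracle equivalence, and the scaled-down NMC search above. These were
  chosen so the whole suite exercises every guarantee in a few minutes on
  one CPU.

## Limitations

- The error model is i.i.d. Gaussian; spatially autocorrelated residuals
  along the network are not modelled and would narrow intervals
  spuriously if present in real data.
- One r is shared by all cover classes; class-specific ranges are not
  estimable at M ≈ 40 and are not offered.
- The per-effect p-values condition on the reduced-model spatial range;
  the p-value for r against the no-LULC null is approximate (boundary
  problem) and should be read qualitatively.
- The NMC module is a null-comparison device; its absolute fit quality
  has no mechanistic interpretation.
- ESRI ASCII grid I/O assumes square cells in degrees and carries no CRS
  beyond geographic lon/lat.
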