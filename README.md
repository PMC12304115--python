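# fishdiv

Spatially explicit attribution of riverine fish species richness to
terrestrial land use and land cover (LULC), with distance-decay
integration over flow-routed catchments.

## The problem

Terrestrial land cover shapes fish communities in rivers through
cross-ecosystem flows of nutrients, sediment, and pollutants, but the two
quantities that matter for management — *how far* upstream land exerts
influence and *how strongly* each cover type acts — are rarely estimated
together. `fishdiv` implements a model for doing exactly that from three
inputs: a D8 flow-direction raster, a categorical land-cover raster
recoded to K classes, and a table of river sites with observed fish
species richness (e.g., from eDNA surveys) and discharge.

## The model

Observed richness at site *i* decomposes into a discharge baseline, the
decay-weighted land-cover exposure of the site's catchment, and Gaussian
error:

    B_i = a + b·ln Q_i + Σ_k V_k c_ik(r) + ε_i,   ε_i ~ N(0, σ²)

    c_ik(r) = (3/r) · Σ_{j: LULC_j = k} A_j · exp(−3 d_ij / r)

where *d_ij* is the flow distance (km) from pixel *j* to site *i*, *A_j*
the pixel area (km²), *V_k* the effect magnitude of cover class *k*, and
*r* the **effective distance**: the upstream range at which influence has
decayed to e⁻³ ≈ 5% of its at-site value. For fixed *r* the maximum
likelihood estimate of (a, b, V) is ordinary least squares on
[1, ln Q, C(r)]; *r* itself is found by profile likelihood (log-spaced
grid plus bounded refinement). Inference comes with likelihood-ratio
tests, profile likelihood-ratio confidence intervals (50%/90%),
adjusted R², leave-one-out cross-validation, site-resampling bootstrap,
and VIF/correlation diagnostics.

Around the core fit the package provides:

- **`synthetic`** — a fully synthetic landscape generator (dendritic D8
  network, autocorrelated LULC mosaic, discharge from area accumulation,
  channel-placed sites, observations at recorded true parameters), so the
  whole pipeline is testable with no proprietary rasters;
- **`hydro`** — catchment delineation with haversine flow distances, flow
  accumulation, major-channel extraction, block resampling;
- **`decay`** — the exponential kernel plus normalized alternative
  families, and the exposure matrix C(r);
- **`species`** — per-species occurrence models (logistic regression on
  the same decay-integrated design, r profiled per species), LULC
  association by the largest effect, and TSS-optimal presence thresholds;
- **`projection`** — per-pixel terrestrial effect maps
  E = V·e^(−3L_ter/r)·(1 − e^(−3L_riv/r)), richness projection along
  major channels, land-cover scenario deltas, Jaccard assemblage
  similarity, bootstrap IQR uncertainty maps;
- **`nmc`** — a simplified neutral meta-community null model (zero-sum
  Moran dynamics on channel reaches, capacity tied to discharge) with
  random-search calibration, for judging how much the land-cover terms
  add over neutral expectations.

## Worked example

```python
import numpy as np
from fishdiv.synthetic import generate_landscape, generate_observations, ModelTruth
from fishdiv.richness import RichnessModel, profile_ci, loocv

truth = ModelTruth(r=19.0, a=20.585, b=3.550,
                   V=np.array([1.438, -0.238, -2.163, -4.857, -3.684]),
                   sigma=5.0)
land = generate_landscape(seed=1)                      # 120x120, 40 sites
obs, record = generate_observations(land, truth, sigma=5.0, seed=2)

model = RichnessModel(B=obs["richness"], Q=obs["discharge"],
                      fields=land.fields, lulc=land.lulc, areas=land.areas)
fit = model.fit(compute_tests=True)
ci = profile_ci(model, fit, "r", level=0.90)
print(f"r = {fit.params.r:.1f} km  (90% CI {ci['lo']:.1f}-{ci['hi']:.1f})")
print(f"adj R2 = {fit.adj_r2:.3f}   -2l = {fit.minus2l:.1f}")
print("V =", np.round(fit.params.V, 2))
```

prints (seeds as above):

```
r = 15.8 km  (90% CI 10.2-22.9)
adj R2 = 0.835   -2l = 230.1
V = [ 2.18  0.18 -1.56 -4.54 -3.82]
```

The fitted effective distance (15.8 km) and effect magnitudes recover the
generating truth (r = 19 km, V as above) within the profile interval; the
adjusted R² says how much of the richness variance the discharge baseline
and the land-cover exposures jointly explain. The same `fit.params` then
drive `projection.effect_map` (species-per-km effect of every terrestrial
pixel) and `projection.project_richness` (expected richness at every
major-channel pixel), whose deltas under alternative LULC rasters give
past/future change maps.

A command-line pipeline wraps the same calls
(`fishdiv simulate | delineate | fit | loocv | bootstrap | effect-map |
project | scenario | species | nmc`); every subcommand takes `--seed` and
writes provenance-stamped artifacts.

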