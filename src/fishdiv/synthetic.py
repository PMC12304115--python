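"""Synthetic landscapes and observations.

Generates, with no external data, the full study substrate the analysis
assumes: a dendritic single-outlet D8 flow network, a spatially
autocorrelated K-class land-cover mosaic, discharge from area
accumulation, channel-placed sampling sites, and site observations drawn
from the Gaussian richness model (and the Bernoulli occurrence model) at
recorded true parameters. Everything is a pure function of its inputs and
an integer seed.

Defaults emulate the study conditions of the motivating system: a 120×120
grid at a nominal 2 km pixel (a ~240 km basin, so that flow distances
dwarf the ~19 km effective distance of land-cover influence, as they do
in large river catchments), five land-cover classes with marginal covers
44/12/36/7/1% (rainfed cropland, irrigated cropland, forest,
shrub-/grassland, urban) in ~16 km patches, and sites on major channel
pixels.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import GridGeoref, LULCRaster, Raster
from .decay import DEFAULT_KERNEL, SiteExposure
from .hydro import (
    D8_NODATA,
    D8_OUTLET,
    OFFSET_TO_CODE,
    DistanceField,
    FlowGrid,
    delineate_catchment,
    extract_channels,
    flow_accumulation,
)

#: nominal 2 km pixel expressed in degrees of a great circle
DEFAULT_CELL_DEG = 2.0 / 111.19493
#: latitude of the default synthetic grid's first row (subtropics)
DEFAULT_LAT0 = 16.0
DEFAULT_LON0 = 100.0

DEFAULT_CLASS_WEIGHTS = (0.44, 0.12, 0.36, 0.07, 0.01)
DEFAULT_LEGEND = {1: "rainfed_cropland", 2: "irrigated_cropland",
                  3: "forest", 4: "shrub_grassland", 5: "urban"}
#: discharge per accumulated area, m³/s per km²
DEFAULT_RUNOFF_COEF = 0.01
#: channel-extraction threshold, pixels of accumulated drainage
DEFAULT_CHANNEL_PIXELS = 15
#: minimum inter-site flow distance, pixels
DEFAULT_MIN_SITE_SPACING = 10


@dataclass
class ModelTruth:
    """True parameters of the Gaussian richness model used for generation."""

    r: float
    a: float
    b: float
    V: np.ndarray
    sigma: float = 0.0

    def as_dict(self) -> dict:
        return {"r": self.r, "a": self.a, "b": self.b,
                "V": list(np.asarray(self.V, float)), "sigma": self.sigma}


@dataclass
class TruthRecord:
    """Ground truth recorded verbatim at generation time; never mutated."""

    theta_true: ModelTruth
    sigma_true: float
    species_params: list[ModelTruth] | None = None
    seed: int | None = None


@dataclass
class SyntheticLandscape:
    flow: FlowGrid
    lulc: LULCRaster
    discharge: Raster
    areas: Raster
    channels: np.ndarray
    sites: pd.DataFrame
    seed: int
    fields: list[DistanceField] = field(default_factory=list)


def _default_georef() -> GridGeoref:
    return GridGeoref(lon0=DEFAULT_LON0, lat0=DEFAULT_LAT0,
                      cell=DEFAULT_CELL_DEG)


def generate_flow_network(n_rows: int, n_cols: int, seed: int,
                          georef: GridGeoref | None = None,
                          tortuosity: float = 1.0) -> FlowGrid:
    """Dendritic single-outlet D8 grid as a random spanning tree.

    The tree is the shortest-path tree from a random border pixel (the
    outlet) under randomized edge costs (step length × a log-normal
    factor): each pixel's D8 code points at its tree parent. This yields
    realistically mildly tortuous flow paths — a uniformly random
    spanning tree would produce space-filling paths many times longer
    than the Euclidean separation, unlike any real drainage network —
    while staying acyclic with every chain terminating at the one outlet.
    ``tortuosity`` is the log-normal sigma of the cost noise (0 gives
    perfectly direct paths; ~1 gives natural-looking meandering).
    """
    if n_rows < 2 or n_cols < 2 or n_rows * n_cols < 4:
        raise ValueError("grid too small to host a spanning tree (need >= 2x2)")
    rng = np.random.default_rng(seed)
    georef = georef or _default_georef()

    # random border outlet
    border = ([(0, c) for c in range(n_cols)]
              + [(n_rows - 1, c) for c in range(n_cols)]
              + [(r, 0) for r in range(1, n_rows - 1)]
              + [(r, n_cols - 1) for r in range(1, n_rows - 1)])
    outlet = border[int(rng.integers(len(border)))]

    codes = np.full((n_rows, n_cols), D8_NODATA, dtype=np.uint8)
    codes[outlet] = D8_OUTLET
    dist = np.full((n_rows, n_cols), np.inf)
    dist[outlet] = 0.0
    done = np.zeros((n_rows, n_cols), dtype=bool)
    heap: list[tuple[float, tuple[int, int], tuple[int, int] | None]] = [
        (0.0, outlet, None)]
    while heap:
        d, (r, c), parent = heapq.heappop(heap)
        if done[r, c]:
            continue
        done[r, c] = True
        if parent is not None:
            codes[r, c] = OFFSET_TO_CODE[(parent[0] - r, parent[1] - c)]
        for (dr, dc) in OFFSET_TO_CODE:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and not done[rr, cc]:
                step = float(np.hypot(dr, dc))
                if tortuosity > 0:
                    step *= float(np.exp(tortuosity
                                         * rng.standard_normal()))
                nd = d + step
                if nd < dist[rr, cc]:
                    dist[rr, cc] = nd
                    heapq.heappush(heap, (nd, (rr, cc), (r, c)))
    return FlowGrid(codes=codes, georef=georef)


def generate_lulc(flow: FlowGrid, n_classes: int = 5,
                  autocorr_scale: float = 8.0,
                  class_weights=DEFAULT_CLASS_WEIGHTS,
                  seed: int = 0,
                  legend: dict[int, str] | None = None) -> LULCRaster:
    """Spatially autocorrelated categorical mosaic with given class covers.

    Gaussian white noise is smoothed at ``autocorr_scale`` pixels,
    rank-transformed to a uniform field, and partitioned at the cumulative
    class weights — so marginal class frequencies match the weights up to
    integer rounding, and patches have correlation length ~ the scale.
    """
    w = np.asarray(class_weights, float)
    if len(w) != n_classes:
        raise ValueError("class_weights length must equal n_classes")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("class weights must be non-negative, not all zero")
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    shape = flow.shape
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=autocorr_scale,
                                     mode="reflect")
    # rank transform -> exactly uniform marginals, then cut at cum weights
    flat = smooth.ravel()
    ranks = stats.rankdata(flat, method="ordinal")
    u = (ranks - 0.5) / flat.size
    cuts = np.cumsum(w)[:-1]
    classes = (np.searchsorted(cuts, u, side="left") + 1).astype(np.int16)
    classes = classes.reshape(shape)
    classes[flow.codes == D8_NODATA] = 0
    if legend is None:
        legend = ({k: DEFAULT_LEGEND.get(k, f"class_{k}")
                   for k in range(1, n_classes + 1)})
    return LULCRaster(raster=Raster(values=classes, georef=flow.georef,
                                    nodata=0), legend=legend)


def synthetic_discharge(flow: FlowGrid, areas: Raster,
                        runoff_coef: float = DEFAULT_RUNOFF_COEF) -> Raster:
    """Discharge Q (m³/s) proportional to accumulated drainage area.

    Q = runoff_coef × accumulated area (km²); monotone non-decreasing
    downstream because accumulation is.
    """
    acc = flow_accumulation(flow, areas)
    return Raster(values=runoff_coef * acc.acc, georef=flow.georef)


def _downstream_chain(flow: FlowGrid, rc, max_steps: int):
    """Pixels on the downstream path from rc (exclusive), with step counts."""
    out = {}
    cur, steps = rc, 0
    while steps < max_steps:
        nxt = flow.successor(*cur)
        if nxt is None:
            break
        steps += 1
        out[nxt] = steps
        cur = nxt
    return out


def place_sites(flow: FlowGrid, channels: np.ndarray, n_sites: int,
                seed: int,
                min_spacing_pixels: int = DEFAULT_MIN_SITE_SPACING
                ) -> list[tuple[int, int]]:
    """Uniform random channel pixels with a minimum inter-site flow distance.

    Two sites constrain each other only if they are flow-connected (one
    lies on the other's downstream path) within ``min_spacing_pixels``
    steps; sites on separate tributaries are unconstrained.
    """
    rng = np.random.default_rng(seed)
    candidates = np.argwhere(channels)
    if len(candidates) < n_sites:
        raise ValueError(
            f"only {len(candidates)} channel pixels for {n_sites} sites")
    order = rng.permutation(len(candidates))
    chosen: list[tuple[int, int]] = []
    chains: list[dict] = []
    for idx in order:
        rc = tuple(int(v) for v in candidates[idx])
        chain = _downstream_chain(flow, rc, min_spacing_pixels)
        ok = all(rc not in ch for ch in chains) and \
            all(s not in chain for s in chosen)
        if ok:
            chosen.append(rc)
            chains.append(chain)
            if len(chosen) == n_sites:
                return chosen
    raise ValueError(
        f"could not place {n_sites} sites at spacing {min_spacing_pixels}")


def generate_landscape(n_rows: int = 120, n_cols: int = 120,
                       n_classes: int = 5, n_sites: int = 40,
                       seed: int = 0,
                       class_weights=DEFAULT_CLASS_WEIGHTS,
                       autocorr_scale: float = 8.0,
                       runoff_coef: float = DEFAULT_RUNOFF_COEF,
                       channel_threshold_pixels: int = DEFAULT_CHANNEL_PIXELS,
                       min_spacing_pixels: int = DEFAULT_MIN_SITE_SPACING,
                       delineate: bool = True) -> SyntheticLandscape:
    """Assemble a full synthetic landscape (flow, LULC, Q, sites, fields)."""
    from .hydro import compute_pixel_areas

    rng = np.random.default_rng(seed)
    s_flow, s_lulc, s_sites = (int(rng.integers(2**31)) for _ in range(3))
    flow = generate_flow_network(n_rows, n_cols, seed=s_flow)
    areas = compute_pixel_areas(flow.georef, flow.shape)
    lulc = generate_lulc(flow, n_classes=n_classes,
                         autocorr_scale=autocorr_scale,
                         class_weights=class_weights, seed=s_lulc)
    acc_px = flow_accumulation(flow, None)
    channels = extract_channels(acc_px, channel_threshold_pixels)
    discharge = synthetic_discharge(flow, areas, runoff_coef)
    rcs = place_sites(flow, channels, n_sites, seed=s_sites,
                      min_spacing_pixels=min_spacing_pixels)
    rows = [rc[0] for rc in rcs]
    cols = [rc[1] for rc in rcs]
    sites = pd.DataFrame({
        "site_id": [f"S{i:03d}" for i in range(len(rcs))],
        "row": rows, "col": cols,
        "lon": flow.georef.lon(np.asarray(cols)),
        "lat": flow.georef.lat(np.asarray(rows)),
        "discharge": discharge.values[rows, cols],
    })
    fields = []
    if delineate:
        fields = [delineate_catchment(flow, rc, site_id=sid)
                  for rc, sid in zip(rcs, sites["site_id"])]
    return SyntheticLandscape(flow=flow, lulc=lulc, discharge=discharge,
                              areas=areas, channels=channels, sites=sites,
                              seed=seed, fields=fields)


def generate_observations(landscape: SyntheticLandscape, theta: ModelTruth,
                          sigma: float, seed: int,
                          round_to_int: bool = False,
                          kernel: str = DEFAULT_KERNEL
                          ) -> tuple[pd.DataFrame, TruthRecord]:
    """Site richness from the Gaussian model at true parameters.

    B_i = a + b·ln Q_i + [C(r) V]_i + ε_i, ε_i ~ N(0, σ²). With
    ``round_to_int`` the values are rounded to the nearest non-negative
    integer (observed richness is a count); default keeps them continuous,
    matching the Gaussian error model.
    """
    if not landscape.fields:
        raise ValueError("landscape has no delineated site fields")
    rng = np.random.default_rng(seed)
    exposure = SiteExposure(landscape.fields, landscape.lulc,
                            landscape.areas, kernel=kernel)
    C = exposure.matrix(theta.r)
    Q = landscape.sites["discharge"].to_numpy()
    mu = theta.a + theta.b * np.log(Q) + C @ np.asarray(theta.V, float)
    B = mu + rng.normal(0.0, sigma, size=mu.shape) if sigma > 0 else mu.copy()
    if round_to_int:
        B = np.maximum(np.rint(B), 0.0)
    obs = landscape.sites.copy()
    obs["richness"] = B
    truth = TruthRecord(theta_true=theta, sigma_true=sigma, seed=seed)
    return obs, truth


def generate_species_occurrence(landscape: SyntheticLandscape,
                                species_params: list[ModelTruth],
                                seed: int,
                                kernel: str = DEFAULT_KERNEL) -> pd.DataFrame:
    """Per-species presence/absence with logit(P) = a + b·ln Q + C(r)·V."""
    if not landscape.fields:
        raise ValueError("landscape has no delineated site fields")
    rng = np.random.default_rng(seed)
    exposure = SiteExposure(landscape.fields, landscape.lulc,
                            landscape.areas, kernel=kernel)
    Q = landscape.sites["discharge"].to_numpy()
    lnQ = np.log(Q)
    out = {"site_id": landscape.sites["site_id"].to_numpy()}
    for s, th in enumerate(species_params):
        C = exposure.matrix(th.r)
        eta = th.a + th.b * lnQ + C @ np.asarray(th.V, float)
        p = 1.0 / (1.0 + np.exp(-eta))
        out[f"sp{s:03d}"] = (rng.random(p.shape) < p).astype(np.int8)
    return pd.DataFrame(out)
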