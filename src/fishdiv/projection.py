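"""Terrestrial effect map, riverine richness projection, scenario deltas.

The effect map assigns every terrestrial pixel j the change in riverine
species richness per km of river that its land cover induces:

    E_j = V_k(j) * exp(-3 L_ter,j / r) * (1 - exp(-3 L_riv,j / r)),

the closed form of integrating the exponential decay density along the
in-river section of pixel j's flow path: L_ter,j is the terrestrial path
length from the pixel to the first major-channel pixel, and L_riv,j the
river path traced downstream from there until the total traced distance
reaches the effective distance r (inclusive truncation at r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LULCRaster, Raster, check_coregistered
from .hydro import FlowGrid, _step_lengths, delineate_catchment
from .decay import DEFAULT_KERNEL
from .richness import ModelParams, RichnessFit, RichnessModel


def effect_closed_form(V: float, L_ter: float, L_riv: float, r: float) -> float:
    """E = V·exp(−3·L_ter/r)·(1 − exp(−3·L_riv/r))."""
    return V * np.exp(-3.0 * L_ter / r) * (1.0 - np.exp(-3.0 * L_riv / r))


@dataclass
class EffectMapGrid:
    """Per-pixel terrestrial effect E (species/km) and path decomposition."""

    E: np.ndarray
    L_ter: np.ndarray
    L_riv: np.ndarray
    georef: object


def effect_map(flow: FlowGrid, channels: np.ndarray, lulc: LULCRaster,
               V, r: float) -> EffectMapGrid:
    """Trace each terrestrial pixel's flow path and evaluate its effect.

    Tracing accumulates pixel-center haversine steps; a pixel whose path
    never reaches a channel within distance r contributes E = 0.
    """
    check_coregistered(flow.codes, channels, lulc.classes)
    V = np.asarray(V, float)
    n_rows, n_cols = flow.shape
    steps = _step_lengths(flow)
    E = np.zeros((n_rows, n_cols))
    L_ter = np.full((n_rows, n_cols), np.nan)
    L_riv = np.full((n_rows, n_cols), np.nan)
    cls = lulc.classes
    for row in range(n_rows):
        for col in range(n_cols):
            k = int(cls[row, col])
            if k <= 0 or channels[row, col]:
                continue
            # terrestrial section: walk to the first channel pixel
            cur = (row, col)
            lter = 0.0
            reached = False
            while lter <= r:
                nxt = flow.successor(*cur)
                if nxt is None:
                    break
                lter += steps[int(flow.codes[cur])][cur[0]]
                cur = nxt
                if channels[cur]:
                    reached = True
                    break
            if not reached or lter > r:
                L_ter[row, col] = lter
                L_riv[row, col] = 0.0
                continue
            # river section: trace along the channel until total reaches r
            lriv = 0.0
            while True:
                nxt = flow.successor(*cur)
                if nxt is None or not channels[nxt]:
                    break
                step = steps[int(flow.codes[cur])][cur[0]]
                if lter + lriv + step > r:
                    lriv = r - lter  # inclusive truncation at r
                    break
                lriv += step
                cur = nxt
            L_ter[row, col] = lter
            L_riv[row, col] = lriv
            E[row, col] = effect_closed_form(V[k - 1], lter, lriv, r)
    return EffectMapGrid(E=E, L_ter=L_ter, L_riv=L_riv, georef=flow.georef)


@dataclass
class RichnessMap:
    """Projected richness per major-channel pixel (NaN elsewhere)."""

    values: np.ndarray
    channels: np.ndarray
    georef: object


def channel_exposures(flow: FlowGrid, channels: np.ndarray,
                      lulc: LULCRaster, areas: Raster, r: float,
                      max_distance: float | None = None,
                      kernel: str = DEFAULT_KERNEL) -> tuple[list, np.ndarray]:
    """Decay-integrated exposures C(r) for every channel pixel.

    ``max_distance`` truncates each local catchment at that flow distance
    (the field practice is r); None keeps the full upstream catchment,
    which reproduces training-site fitted values exactly.
    """
    rcs = [tuple(rc) for rc in np.argwhere(channels)]
    rows = np.zeros((len(rcs), lulc.n_classes))
    cls = lulc.classes
    for i, rc in enumerate(rcs):
        df = delineate_catchment(flow, rc, site_id=f"px{i}")
        m = df.member & (cls > 0)
        if max_distance is not None:
            m &= df.d_km <= max_distance
        d = df.d_km[m]
        a = areas.values[m]
        k = cls[m]
        from .decay import DecayKernel, kernel_eval
        w = a * kernel_eval(DecayKernel(r, kernel), d)
        rows[i] = np.bincount(k - 1, weights=w, minlength=lulc.n_classes)
    return rcs, rows


def project_richness(channels: np.ndarray, flow: FlowGrid, lulc: LULCRaster,
                     areas: Raster, params: ModelParams, discharge: Raster,
                     max_distance: float | None = None) -> RichnessMap:
    """Project mu = a + b ln Q + C(r)·V at every major-channel pixel."""
    check_coregistered(flow.codes, channels, lulc.classes, areas.values,
                       discharge.values)
    rcs, C = channel_exposures(flow, channels, lulc, areas, params.r,
                               max_distance=max_distance)
    out = np.full(flow.shape, np.nan)
    for (rr, cc), c_row in zip(rcs, C):
        q = discharge.values[rr, cc]
        if not np.isfinite(q) or q <= 0:
            continue  # flagged nodata
        out[rr, cc] = params.a + params.b * np.log(q) + c_row @ params.V
    return RichnessMap(values=out, channels=channels, georef=flow.georef)


@dataclass
class ScenarioDelta:
    percent: np.ndarray
    mean: float
    min: float
    max: float


def scenario_delta(map_old: RichnessMap, map_new: RichnessMap) -> ScenarioDelta:
    """Percent change per channel pixel: 100·(new − old)/old; old=0 → NaN."""
    check_coregistered(map_old.values, map_new.values)
    old, new = map_old.values, map_new.values
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where((old != 0) & np.isfinite(old) & np.isfinite(new),
                       100.0 * (new - old) / old, np.nan)
    valid = pct[np.isfinite(pct)]
    return ScenarioDelta(percent=pct,
                         mean=float(valid.mean()) if valid.size else np.nan,
                         min=float(valid.min()) if valid.size else np.nan,
                         max=float(valid.max()) if valid.size else np.nan)


def merge_lulc_classes(lulc: LULCRaster, merge_spec: dict[int, int]) -> LULCRaster:
    """Relabel classes by ``merge_spec`` (old → new); new labels must be 1..K'."""
    targets = sorted(set(merge_spec.values()))
    if targets != list(range(1, len(targets) + 1)):
        raise ValueError(
            f"merge spec must map onto contiguous classes 1..K', got {targets}")
    present = set(np.unique(lulc.classes)) - {0}
    missing = present - set(merge_spec)
    if missing:
        raise ValueError(f"merge spec does not cover classes {sorted(missing)}")
    new = np.zeros_like(lulc.classes)
    for old, tgt in merge_spec.items():
        new[lulc.classes == old] = tgt
    legend = {}
    for old, tgt in merge_spec.items():
        name = lulc.legend.get(old, f"class_{old}")
        legend[tgt] = (legend[tgt] + "+" + name) if tgt in legend else name
    from .core import Raster as _R
    return LULCRaster(raster=_R(values=new, georef=lulc.raster.georef,
                                nodata=0), legend=legend)


def refit_merged_classes(obs, fields, lulc: LULCRaster, areas: Raster,
                         merge_spec: dict[int, int],
                         **fit_kw) -> tuple[RichnessFit, LULCRaster]:
    """Merge LULC classes (K reduced) and refit the richness model."""
    merged = merge_lulc_classes(lulc, merge_spec)
    model = RichnessModel(B=obs["richness"].to_numpy(),
                          Q=obs["discharge"].to_numpy(),
                          fields=fields, lulc=merged, areas=areas, **fit_kw)
    return model.fit(), merged


def jaccard(set_a, set_b) -> float:
    """|A∩B| / |A∪B|; two empty assemblages count as identical (J = 1)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def bootstrap_maps(draws, project_one, q25: float = 25.0,
                   q75: float = 75.0) -> np.ndarray:
    """Per-pixel IQR of maps projected from bootstrap parameter draws.

    ``draws`` is a DataFrame of parameter draws (bootstrap_params output);
    ``project_one(params: ModelParams) -> ndarray`` renders one map.
    """
    if len(draws) < 4:
        raise ValueError("need at least 4 draws for an interquartile range")
    maps = []
    for _, row in draws.iterrows():
        V = np.array([row[c] for c in draws.columns if c.startswith("V")])
        params = ModelParams(r=row["r"], a=row["a"], b=row["b"], V=V,
                             sigma=row.get("sigma", 0.0))
        maps.append(project_one(params))
    stack = np.stack(maps)
    return np.nanpercentile(stack, q75, axis=0) - \
        np.nanpercentile(stack, q25, axis=0)
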