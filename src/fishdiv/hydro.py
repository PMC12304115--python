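"""D8 raster hydrology.

Catchment delineation with flow distances, haversine pixel areas, flow
accumulation, and major-channel extraction on D8 flow-direction grids.

D8 encoding follows the ESRI power-of-two convention:

    32  64  128
    16   .    1
     8   4    2

i.e. 1 = east, 2 = south-east, ... 128 = north-east; 0 marks the outlet
(terminal pixel) and 255 marks nodata. A pixel whose successor falls off
the grid or onto nodata is treated as draining to an external outlet: its
water leaves the study area and it never joins any site's catchment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EARTH_RADIUS_KM, GridGeoref, Raster, check_coregistered

D8_OUTLET = 0
D8_NODATA = 255

# code -> (drow, dcol)
D8_OFFSETS: dict[int, tuple[int, int]] = {
    1: (0, 1),
    2: (1, 1),
    4: (1, 0),
    8: (1, -1),
    16: (0, -1),
    32: (-1, -1),
    64: (-1, 0),
    128: (-1, 1),
}
OFFSET_TO_CODE = {v: k for k, v in D8_OFFSETS.items()}
VALID_CODES = frozenset(D8_OFFSETS) | {D8_OUTLET, D8_NODATA}


@dataclass
class FlowGrid:
    """D8 flow-direction raster (see module docstring for the encoding)."""

    codes: np.ndarray
    georef: GridGeoref

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def validate(self) -> None:
        bad = set(np.unique(self.codes)) - VALID_CODES
        if bad:
            raise ValueError(f"invalid D8 codes present: {sorted(bad)}")

    def successor(self, row: int, col: int) -> tuple[int, int] | None:
        """Downstream neighbor of (row, col), or None at outlet/edge/nodata."""
        code = int(self.codes[row, col])
        if code in (D8_OUTLET, D8_NODATA):
            return None
        dr, dc = D8_OFFSETS[code]
        r, c = row + dr, col + dc
        n_rows, n_cols = self.shape
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            return None
        if self.codes[r, c] == D8_NODATA:
            return None
        return r, c


@dataclass
class DistanceField:
    """Per-site catchment membership with flow distances.

    ``d_km[r, c]`` is the along-flow-path distance (km) from pixel (r, c)
    to the site; NaN outside the catchment; 0 at the site pixel itself.
    """

    site_id: str
    site_rc: tuple[int, int]
    d_km: np.ndarray
    georef: GridGeoref

    @property
    def member(self) -> np.ndarray:
        return np.isfinite(self.d_km)

    @property
    def max_distance(self) -> float:
        m = self.member
        return float(self.d_km[m].max()) if m.any() else float("nan")


@dataclass
class DrainageGrid:
    """Accumulated upstream area per pixel (km², or pixel counts)."""

    acc: np.ndarray
    georef: GridGeoref
    units: str = "km2"


def haversine_distance(lon1, lat1, lon2, lat2):
    """Great-circle distance in km on a sphere of radius 6371 km.

    Accepts scalars or broadcastable arrays of degrees.
    """
    lat1a, lat2a = np.asarray(lat1, float), np.asarray(lat2, float)
    if np.any(np.abs(lat1a) > 90) or np.any(np.abs(lat2a) > 90):
        raise ValueError("latitude out of [-90, 90]")
    p1, p2 = np.radians(lat1a), np.radians(lat2a)
    dp = p2 - p1
    dl = np.radians(np.asarray(lon2, float) - np.asarray(lon1, float))
    h = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    out = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def compute_pixel_areas(georef: GridGeoref, shape: tuple[int, int]) -> Raster:
    """Pixel areas A_j (km²) = haversine EW width at pixel latitude × NS height.

    Width depends only on latitude for a fixed cell size, so one value is
    computed per row and broadcast across columns.
    """
    n_rows, n_cols = shape
    lats = georef.lat(np.arange(n_rows))
    widths = haversine_distance(0.0, lats, georef.cell, lats)
    heights = haversine_distance(0.0, lats - georef.cell / 2.0,
                                 0.0, lats + georef.cell / 2.0)
    areas = np.repeat((widths * heights)[:, None], n_cols, axis=1)
    return Raster(values=areas, georef=georef)


def _step_lengths(flow: FlowGrid) -> dict[int, np.ndarray]:
    """Per-row haversine step length (km) for each D8 code."""
    n_rows, _ = flow.shape
    rows = np.arange(n_rows)
    lats = flow.georef.lat(rows)
    cell = flow.georef.cell
    out = {}
    for code, (dr, dc) in D8_OFFSETS.items():
        lat2 = lats - dr * cell
        out[code] = haversine_distance(0.0, lats, dc * cell, lat2)
    return out


def _children(flow: FlowGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reverse adjacency as flat arrays.

    Returns (child_flat, parent_flat, step_km): for every pixel with a
    valid in-grid successor, its flat index, the successor's flat index,
    and the haversine center-to-center step length.
    """
    n_rows, n_cols = flow.shape
    codes = flow.codes
    steps = _step_lengths(flow)
    child, parent, dist = [], [], []
    for code, (dr, dc) in D8_OFFSETS.items():
        rr, cc = np.nonzero(codes == code)
        if rr.size == 0:
            continue
        r2, c2 = rr + dr, cc + dc
        ok = (r2 >= 0) & (r2 < n_rows) & (c2 >= 0) & (c2 < n_cols)
        rr, cc, r2, c2 = rr[ok], cc[ok], r2[ok], c2[ok]
        ok2 = codes[r2, c2] != D8_NODATA
        rr, cc, r2, c2 = rr[ok2], cc[ok2], r2[ok2], c2[ok2]
        child.append(rr * n_cols + cc)
        parent.append(r2 * n_cols + c2)
        dist.append(steps[code][rr])
    if not child:
        z = np.zeros(0, dtype=np.int64)
        return z, z, np.zeros(0)
    return (np.concatenate(child), np.concatenate(parent),
            np.concatenate(dist))


def delineate_catchment(flow: FlowGrid, site_rc: tuple[int, int],
                        site_id: str = "site") -> DistanceField:
    """All pixels whose flow path passes through ``site_rc``, with distances.

    Flow distance is the cumulative sum of haversine center-to-center
    steps (diagonals use the true diagonal center distance) from the
    pixel down to the site; 0 at the site itself.
    """
    n_rows, n_cols = flow.shape
    r0, c0 = site_rc
    if flow.codes[r0, c0] == D8_NODATA:
        raise ValueError(f"site pixel {site_rc} is nodata")
    child, parent, step = _children(flow)
    order = np.argsort(parent, kind="stable")
    child, parent, step = child[order], parent[order], step[order]
    starts = np.searchsorted(parent, np.arange(n_rows * n_cols))
    ends = np.searchsorted(parent, np.arange(n_rows * n_cols) + 1)

    d = np.full(n_rows * n_cols, np.nan)
    root = r0 * n_cols + c0
    d[root] = 0.0
    stack = [root]
    while stack:
        p = stack.pop()
        for idx in range(starts[p], ends[p]):
            ch = child[idx]
            d[ch] = d[p] + step[idx]
            stack.append(ch)
    return DistanceField(site_id=site_id, site_rc=(r0, c0),
                         d_km=d.reshape(n_rows, n_cols), georef=flow.georef)


def delineate_sites(flow: FlowGrid, sites) -> list[DistanceField]:
    """Delineate a DistanceField for each row of a sites table.

    ``sites`` is any iterable of records with .site_id, .row, .col
    (e.g. pandas itertuples) or (site_id, row, col) tuples.
    """
    fields = []
    for rec in sites:
        if hasattr(rec, "site_id"):
            sid, r, c = rec.site_id, int(rec.row), int(rec.col)
        else:
            sid, r, c = rec[0], int(rec[1]), int(rec[2])
        fields.append(delineate_catchment(flow, (r, c), site_id=str(sid)))
    return fields


class FlowCycleError(RuntimeError):
    pass


def flow_accumulation(flow: FlowGrid, areas: Raster | None = None) -> DrainageGrid:
    """Topological-order accumulation: own area plus everything upstream.

    With ``areas=None`` accumulates pixel counts instead of km².
    Raises FlowCycleError naming a pixel if the grid contains a cycle.
    """
    n_rows, n_cols = flow.shape
    n = n_rows * n_cols
    if areas is None:
        own = np.ones(n)
        units = "pixels"
    else:
        check_coregistered(flow.codes, areas.values)
        own = areas.values.reshape(n).astype(float)
        units = "km2"
    nodata = (flow.codes == D8_NODATA).reshape(n)
    own = np.where(nodata, 0.0, own)

    child, parent, _ = _children(flow)
    succ = np.full(n, -1, dtype=np.int64)
    succ[child] = parent
    indeg = np.bincount(parent, minlength=n)

    acc = own.copy()
    queue = list(np.nonzero((indeg == 0) & ~nodata)[0])
    processed = np.zeros(n, dtype=bool)
    processed[nodata] = True
    count = 0
    while queue:
        p = queue.pop()
        processed[p] = True
        count += 1
        s = succ[p]
        if s >= 0:
            acc[s] += acc[p]
            indeg[s] -= 1
            if indeg[s] == 0:
                queue.append(s)
    if count < int((~nodata).sum()):
        bad = int(np.nonzero(~processed)[0][0])
        raise FlowCycleError(
            f"cycle detected involving pixel {divmod(bad, n_cols)}")
    acc[nodata] = np.nan
    return DrainageGrid(acc=acc.reshape(n_rows, n_cols),
                        georef=flow.georef, units=units)


def extract_channels(acc: DrainageGrid, threshold: float) -> np.ndarray:
    """Boolean mask of major-channel pixels: accumulation ≥ threshold."""
    if threshold < 0:
        raise ValueError("threshold must be positive")
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(acc.acc), False, acc.acc >= threshold)


def snap_to_channel(channels: np.ndarray, rc: tuple[int, int],
                    radius: int = 5) -> tuple[int, int]:
    """Snap a pixel to the nearest channel pixel within ``radius`` pixels."""
    r0, c0 = rc
    if channels[r0, c0]:
        return (r0, c0)
    n_rows, n_cols = channels.shape
    best, best_d2 = None, (radius + 1) ** 2
    for r in range(max(0, r0 - radius), min(n_rows, r0 + radius + 1)):
        for c in range(max(0, c0 - radius), min(n_cols, c0 + radius + 1)):
            if channels[r, c]:
                d2 = (r - r0) ** 2 + (c - c0) ** 2
                if d2 < best_d2:
                    best, best_d2 = (r, c), d2
    if best is None:
        raise ValueError(f"no channel pixel within {radius} pixels of {rc}")
    return best


def resample_distance_field(df: DistanceField, factor: int,
                            how: str = "mean") -> DistanceField:
    """Block-aggregate a DistanceField by an integer factor.

    Membership by majority of the block's pixels; the coarse distance is
    the block mean over member pixels (``how='mean'``) or the fine value
    at the block center (``how='nearest'``).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return df
    n_rows, n_cols = df.d_km.shape
    nr, nc = -(-n_rows // factor), -(-n_cols // factor)
    pad_r, pad_c = nr * factor - n_rows, nc * factor - n_cols
    d = np.pad(df.d_km, ((0, pad_r), (0, pad_c)), constant_values=np.nan)
    blocks = d.reshape(nr, factor, nc, factor).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(nr, nc, factor * factor)
    member_counts = np.isfinite(blocks).sum(axis=2)
    member = member_counts * 2 > factor * factor
    if how == "mean":
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            vals = np.nanmean(blocks, axis=2)
    elif how == "nearest":
        vals = blocks[:, :, (factor // 2) * factor + factor // 2]
    else:
        raise ValueError(f"unknown aggregation {how!r}")
    coarse = np.where(member, vals, np.nan)
    g = df.georef
    new_georef = GridGeoref(
        lon0=g.lon0 + (factor - 1) / 2.0 * g.cell,
        lat0=g.lat0 - (factor - 1) / 2.0 * g.cell,
        cell=g.cell * factor,
    )
    return DistanceField(site_id=df.site_id,
                         site_rc=(df.site_rc[0] // factor,
                                  df.site_rc[1] // factor),
                         d_km=coarse, georef=new_georef)
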