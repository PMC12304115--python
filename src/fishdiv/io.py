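"""File formats, LULC recoding, and run configuration.

Rasters travel as ESRI ASCII grids (.asc): a plain-text header (ncols,
nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
whitespace-separated rows, north row first — matching the package's
in-memory convention. Square cells in degrees. Sites and observations are
CSV; fits, truth records, and NMC results are JSON. Every artifact
carries a provenance record (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import GridGeoref, LULCRaster, Raster
from .hydro import FlowGrid

PACKAGE_VERSION = "0.1.0"


def provenance(seed: int | None = None, config: dict | None = None) -> dict:
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "package": f"fishdiv {PACKAGE_VERSION}",
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
    }


# ------------------------------ rasters ------------------------------

def write_raster(path, raster: Raster, fmt: str = "%.10g") -> None:
    """Write a Raster as an ESRI ASCII grid (+ .prov.json sidecar)."""
    path = Path(path)
    n_rows, n_cols = raster.shape
    g = raster.georef
    nodata = raster.nodata if raster.nodata is not None else -9999
    header = (f"ncols {n_cols}\nnrows {n_rows}\n"
              f"xllcorner {float(g.lon0 - g.cell / 2)!r}\n"
              f"yllcorner {float(g.lat(n_rows - 1) - g.cell / 2)!r}\n"
              f"cellsize {float(g.cell)!r}\nNODATA_value {nodata}\n")
    vals = raster.values
    if raster.nodata is None:
        vals = np.where(np.isfinite(vals), vals, -9999)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)
    with open(path.with_suffix(path.suffix + ".prov.json"), "w") as fh:
        json.dump(provenance(config={"file": path.name}), fh)


def read_raster(path, dtype=float) -> Raster:
    """Read an ESRI ASCII grid back into a Raster."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"}:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing georeferencing field {req!r}")
    values = np.loadtxt(lines[i:], dtype=dtype)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(n_rows, n_cols)
    cell = header["cellsize"]
    georef = GridGeoref(lon0=header["xllcorner"] + cell / 2,
                        lat0=header["yllcorner"] + cell / 2
                        + (n_rows - 1) * cell,
                        cell=cell)
    nodata = header.get("nodata_value")
    if nodata is not None and np.issubdtype(np.asarray(values).dtype,
                                            np.integer):
        nodata = int(nodata)
    return Raster(values=values, georef=georef, nodata=nodata)


def write_flow(path, flow: FlowGrid) -> None:
    write_raster(path, Raster(values=flow.codes.astype(int),
                              georef=flow.georef, nodata=255), fmt="%d")


def read_flow(path) -> FlowGrid:
    r = read_raster(path, dtype=int)
    flow = FlowGrid(codes=r.values.astype(np.uint8), georef=r.georef)
    flow.validate()
    return flow


# ----------------------------- site tables -----------------------------

SITE_COLUMNS = ["site_id", "row", "col", "lon", "lat", "richness",
                "discharge"]


def write_sites_csv(path, sites: pd.DataFrame, seed: int | None = None,
                    config: dict | None = None) -> None:
    prov = provenance(seed=seed, config=config)
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(prov)}\n")
        sites.to_csv(fh, index=False)


def read_sites_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(path, obj, seed: int | None = None,
               config: dict | None = None) -> None:
    payload = dict(obj)
    payload["_provenance"] = provenance(seed=seed, config=config)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    if hasattr(o, "as_dict"):
        return o.as_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


# ----------------------------- LULC recode -----------------------------

@dataclass
class RecodeTable:
    """Source land-cover codes → target classes 1..K, plus dropped codes."""

    mapping: dict[int, int]
    drop: frozenset[int] = frozenset()
    legend: dict[int, str] | None = None

    def __post_init__(self):
        targets = sorted(set(self.mapping.values()))
        if targets != list(range(1, len(targets) + 1)):
            raise ValueError(
                f"target classes must be contiguous 1..K, got {targets}")


def recode_lulc(raster: Raster, table: RecodeTable) -> tuple[LULCRaster, dict]:
    """Apply a recode table; dropped codes (e.g. water) become nodata (0).

    Returns the recoded LULCRaster and a class-frequency report over
    non-dropped pixels (frequencies sum to 1).
    """
    src = raster.values.astype(int)
    present = set(np.unique(src).tolist())
    if raster.nodata is not None:
        present -= {int(raster.nodata)}
    unmapped = present - set(table.mapping) - set(table.drop)
    if unmapped:
        raise ValueError(f"unmapped land-cover codes: {sorted(unmapped)}")
    out = np.zeros_like(src)
    for code, target in table.mapping.items():
        out[src == code] = target
    if raster.nodata is not None:
        out[src == int(raster.nodata)] = 0
    lulc = LULCRaster(raster=Raster(values=out, georef=raster.georef,
                                    nodata=0), legend=table.legend or {})
    kept = out[out > 0]
    freqs = {int(k): float(np.mean(kept == k))
             for k in sorted(np.unique(kept))} if kept.size else {}
    return lulc, freqs


#: default recode: identity over the five target covers
DEFAULT_RECODE = RecodeTable(
    mapping={1: 1, 2: 2, 3: 3, 4: 4, 5: 5},
    drop=frozenset({0}),
    legend={1: "rainfed_cropland", 2: "irrigated_cropland", 3: "forest",
            4: "shrub_grassland", 5: "urban"},
)


# ------------------------------- config -------------------------------

@dataclass
class RunConfig:
    kernel: str = "exponential"
    r_min: float = 1.0
    r_max: float = 500.0
    n_grid: int = 60
    likelihood: str = "gaussian"
    n_boot: int = 2000
    channel_threshold: float = 50.0      # pixels of accumulated drainage
    snap_radius: int = 5
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.r_min <= 0 or self.r_max <= self.r_min:
            raise ValueError("need 0 < r_min < r_max")
        if self.kernel not in ("exponential", "half_normal", "linear_taper",
                               "uniform_window", "inverse_power"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.likelihood not in ("gaussian",):
            raise ValueError(f"unsupported likelihood {self.likelihood!r}")
        return self

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data).validate()
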