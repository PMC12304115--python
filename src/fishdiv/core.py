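"""Grid georeferencing and raster containers.

All rasters in the package share one convention: 0-based (row, col)
indexing, row-major storage, pixel-center georeferencing on a geographic
(lon/lat, degrees) grid with square cells. Row 0 is the northernmost row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridGeoref:
    """Affine pixel-center georeferencing for a north-up geographic grid.

    Parameters
    ----------
    lon0, lat0 : float
        Longitude/latitude of the center of pixel (0, 0), degrees.
    cell : float
        Cell size in degrees (square cells; latitude decreases with row).
    """

    lon0: float
    lat0: float
    cell: float

    def lon(self, col):
        return self.lon0 + np.asarray(col) * self.cell

    def lat(self, row):
        return self.lat0 - np.asarray(row) * self.cell

    def lonlat(self, row, col):
        return self.lon(col), self.lat(row)


@dataclass
class Raster:
    """A single-band raster: values + georeferencing + optional nodata."""

    values: np.ndarray
    georef: GridGeoref
    nodata: float | int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) pixels."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        return self.values != self.nodata


@dataclass
class LULCRaster:
    """Categorical land-use/land-cover raster with K classes.

    Class labels run 1..K; 0 marks excluded pixels (water and other
    dropped covers, which route flow but carry no terrestrial exposure).
    """

    raster: Raster
    legend: dict[int, str] = field(default_factory=dict)

    @property
    def classes(self) -> np.ndarray:
        return self.raster.values

    @property
    def n_classes(self) -> int:
        if self.legend:
            return max(self.legend)
        valid = self.classes[self.classes > 0]
        return int(valid.max()) if valid.size else 0


class GridMismatchError(ValueError):
    pass


def check_coregistered(*shapes_or_rasters) -> None:
    """Raise GridMismatchError unless all inputs share one grid shape."""
    shapes = []
    for obj in shapes_or_rasters:
        if hasattr(obj, "shape"):
            shapes.append(tuple(obj.shape))
        else:
            shapes.append(tuple(obj))
    first = shapes[0]
    for s in shapes[1:]:
        if s != first:
            raise GridMismatchError(
                f"rasters are not co-registered: shapes {first} vs {s}"
            )
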