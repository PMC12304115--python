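import numpy as np
import pytest

from fishdiv.core import GridGeoref, LULCRaster, Raster
from fishdiv.hydro import D8_OUTLET, FlowGrid
from fishdiv.synthetic import ModelTruth, generate_landscape

#: effect magnitudes and scale of the reference fit used as generator truth
TRUTH = ModelTruth(r=19.0, a=20.585, b=3.550,
                   V=np.array([1.438, -0.238, -2.163, -4.857, -3.684]),
                   sigma=5.0)


@pytest.fixture(scope="session")
def truth():
    return TRUTH


@pytest.fixture(scope="session")
def small_landscape():
    """A 60x60 landscape with 12 channel sites; shared across tests."""
    return generate_landscape(60, 60, n_sites=12, seed=11)


@pytest.fixture(scope="session")
def default_landscape():
    """The full default study landscape (120x120, 40 sites)."""
    return generate_landscape(seed=42)


def make_chain_flow(n: int, cell: float = 2.0 / 111.19493,
                    lat0: float = 16.0) -> FlowGrid:
    """A 1 x n west->east chain; the outlet is the easternmost pixel."""
    codes = np.full((1, n), 1, dtype=np.uint8)  # 1 = east
    codes[0, n - 1] = D8_OUTLET
    return FlowGrid(codes=codes,
                    georef=GridGeoref(lon0=100.0, lat0=lat0, cell=cell))


def walk_to_outlet(flow: FlowGrid, rc, max_steps=None):
    """Brute-force D8 walker; returns (path, reached_terminal)."""
    n = flow.shape[0] * flow.shape[1]
    max_steps = max_steps or n + 1
    path = [rc]
    cur = rc
    for _ in range(max_steps):
        nxt = flow.successor(*cur)
        if nxt is None:
            return path, True
        cur = nxt
        path.append(cur)
    return path, False


def oracle_distance_field(flow: FlowGrid, site_rc):
    """Independent per-pixel path-following oracle for catchment distances."""
    from fishdiv.hydro import haversine_distance

    n_rows, n_cols = flow.shape
    d = np.full((n_rows, n_cols), np.nan)
    g = flow.georef
    for r in range(n_rows):
        for c in range(n_cols):
            cur = (r, c)
            dist = 0.0
            for _ in range(n_rows * n_cols + 1):
                if cur == tuple(site_rc):
                    d[r, c] = dist
                    break
                nxt = flow.successor(*cur)
                if nxt is None:
                    break
                dist += haversine_distance(g.lon(cur[1]), g.lat(cur[0]),
                                           g.lon(nxt[1]), g.lat(nxt[0]))
                cur = nxt
    return d


def naive_effect_matrix(fields, lulc: LULCRaster, areas: Raster, r: float):
    """Per-pixel loop evaluation of the exposure matrix (test oracle)."""
    K = lulc.n_classes
    out = np.zeros((len(fields), K))
    for i, f in enumerate(fields):
        n_rows, n_cols = f.d_km.shape
        for rr in range(n_rows):
            for cc in range(n_cols):
                d = f.d_km[rr, cc]
                k = int(lulc.classes[rr, cc])
                if np.isfinite(d) and k > 0:
                    out[i, k - 1] += (areas.values[rr, cc]
                                      * (3.0 / r) * np.exp(-3.0 * d / r))
    return out
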