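"""Dispersal covariance matrices from center-to-site distances.

A dispersal scenario for a region is summarised by distances from a candidate
diffusion center to each sampling site (``d_center``) and between sites
(``d_pair``), under either straight geodesic distance ("linear") or
least-cost routes over a landscape ("routes"). If spread followed a
binary-branching path tree rooted at the center, the covariance of two sites'
drift equals their shared root-to-fork path length; for an additive tree that
shared length is exactly ``(d1 + d2 - x) / 2`` with ``d1, d2`` the
center-to-site distances and ``x`` the inter-site distance. The same formula
is used as a heuristic when the true path tree is unknown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .io_geno import SiteSet

__all__ = [
    "DistanceSpec",
    "DispersalCovariance",
    "CostRaster",
    "candidate_centers",
    "haversine_km",
    "linear_distances",
    "least_cost_distances",
    "shared_path_covariance",
    "heuristic_covariance",
    "read_ascii_grid",
    "read_distance_matrix",
    "write_distance_matrix",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceSpec:
    """Distances defining one dispersal scenario for one candidate center."""

    d_center: np.ndarray  # [M] center -> site
    d_pair: np.ndarray  # [M, M] site <-> site, symmetric, zero diagonal
    scenario_label: str  # "routes" | "linear" | free-form

    def __post_init__(self) -> None:
        self.d_center = np.asarray(self.d_center, dtype=float)
        self.d_pair = np.asarray(self.d_pair, dtype=float)
        m = self.d_center.shape[0]
        if self.d_pair.shape != (m, m):
            raise ValueError("d_pair shape does not match d_center")
        if (self.d_center < 0).any() or (self.d_pair < 0).any():
            raise ValueError("distances must be nonnegative")
        if not np.allclose(self.d_pair, self.d_pair.T, atol=1e-8):
            raise ValueError("d_pair must be symmetric")
        if not np.allclose(np.diag(self.d_pair), 0, atol=1e-8):
            raise ValueError("d_pair must have zero diagonal")


@dataclass
class DispersalCovariance:
    """Site covariance matrix V for one dispersal scenario; after scaling the
    diagonal averages one, so drift amounts are relative to the regional
    mean root-to-site path."""

    V: np.ndarray
    scale_applied: bool
    scenario_label: str = ""

    @property
    def n_sites(self) -> int:
        return self.V.shape[0]


def candidate_centers(sites: SiteSet, grid: int = 4, margin: float = 0.1) -> np.ndarray:
    """Candidate diffusion centers on an even ``grid × grid`` inside the
    bounding rectangle of the sites, shrunk by ``margin`` of each side length.

    Returns an array of (lon, lat) rows, ``grid**2`` of them.
    """
    if len(sites) < 2:
        raise ValueError("need at least two sites to span a rectangle")
    lo_w, lo_e = float(sites.lon.min()), float(sites.lon.max())
    la_s, la_n = float(sites.lat.min()), float(sites.lat.max())
    if lo_w == lo_e and la_s == la_n:
        warnings.warn("all sites coincident; single candidate center", stacklevel=2)
        return np.array([[lo_w, la_s]])
    dx, dy = lo_e - lo_w, la_n - la_s
    lo_w, lo_e = lo_w + margin * dx, lo_e - margin * dx
    la_s, la_n = la_s + margin * dy, la_n - margin * dy
    if grid == 1:
        return np.array([[(lo_w + lo_e) / 2, (la_s + la_n) / 2]])
    lons = np.linspace(lo_w, lo_e, grid)
    lats = np.linspace(la_s, la_n, grid)
    gg = np.meshgrid(lons, lats)
    return np.column_stack([gg[0].ravel(), gg[1].ravel()])


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (haversine, spherical Earth R = 6371 km)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def linear_distances(sites: SiteSet, center) -> DistanceSpec:
    """Geodesic (great-circle) distances, km, scenario label "linear"."""
    clon, clat = float(center[0]), float(center[1])
    d_center = haversine_km(sites.lon, sites.lat, clon, clat)
    d_pair = haversine_km(
        sites.lon[:, None], sites.lat[:, None], sites.lon[None, :], sites.lat[None, :]
    )
    d_pair = 0.5 * (d_pair + d_pair.T)
    np.fill_diagonal(d_pair, 0.0)
    return DistanceSpec(d_center, d_pair, "linear")


@dataclass
class CostRaster:
    """Per-cell traversal costs on a regular lon/lat grid.

    ``cost[r, c]`` is the cost of crossing cell (r, c); row 0 is the
    northernmost row (ESRI ASCII convention). ``np.inf`` marks impassable
    cells. ``xll, yll`` georeference the lower-left corner; ``cellsize`` is in
    degrees (converted to km at the raster's mean latitude for step lengths).
    """

    cost: np.ndarray
    xll: float
    yll: float
    cellsize: float

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        nrows = self.cost.shape[0]
        c = int(np.floor((lon - self.xll) / self.cellsize))
        r = nrows - 1 - int(np.floor((lat - self.yll) / self.cellsize))
        if not (0 <= r < nrows and 0 <= c < self.cost.shape[1]):
            raise ValueError(f"point ({lon}, {lat}) outside raster extent")
        return r, c


def read_ascii_grid(path) -> CostRaster:
    """Read an ESRI ASCII grid (.asc). ``nodata`` cells become infinite cost."""
    hdr: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                hdr[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    cost = np.array(rows, dtype=float)
    if "nodata_value" in hdr:
        cost[cost == hdr["nodata_value"]] = np.inf
    if cost.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
        raise ValueError("ASCII grid shape does not match header")
    return CostRaster(cost, hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"])


def _raster_graph(raster: CostRaster, step_km: float):
    """Sparse 8-connected lattice; edge weight = mean endpoint cost × step."""
    cost = raster.cost
    nrows, ncols = cost.shape
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)
    src, dst, wgt = [], [], []
    moves = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))]
    for dr, dc, mult in moves:
        r0 = slice(0, nrows - dr)
        r1 = slice(dr, nrows)
        if dc >= 0:
            c0, c1 = slice(0, ncols - dc), slice(dc, ncols)
        else:
            c0, c1 = slice(-dc, ncols), slice(0, ncols + dc)
        a = idx[r0, c0].ravel()
        b = idx[r1, c1].ravel()
        w = 0.5 * (cost[r0, c0].ravel() + cost[r1, c1].ravel()) * mult * step_km
        ok = np.isfinite(w)
        src.append(a[ok])
        dst.append(b[ok])
        wgt.append(w[ok])
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    wgt = np.concatenate(wgt)
    n = nrows * ncols
    return coo_matrix((wgt, (src, dst)), shape=(n, n)).tocsr()


def least_cost_distances(raster: CostRaster, sites: SiteSet, center) -> DistanceSpec:
    """Least-cost-path distances over ``raster`` (8-connected Dijkstra).

    Edge weights are the mean of the two endpoint cell costs times the step
    length (diagonal steps × sqrt(2)); step length is the cell size converted
    to km at the raster's mean latitude. Scenario label "routes".
    """
    mean_lat = raster.yll + 0.5 * raster.cost.shape[0] * raster.cellsize
    step_km = raster.cellsize * (np.pi / 180) * EARTH_RADIUS_KM * np.cos(np.radians(mean_lat))
    ncols = raster.cost.shape[1]
    nodes = []
    for sid, lo, la in zip(sites.site_ids, sites.lon, sites.lat):
        r, c = raster.cell_of(lo, la)
        if not np.isfinite(raster.cost[r, c]):
            raise ValueError(f"site {sid} lies on an impassable raster cell")
        nodes.append(r * ncols + c)
    rc, cc = raster.cell_of(float(center[0]), float(center[1]))
    if not np.isfinite(raster.cost[rc, cc]):
        raise ValueError("center lies on an impassable raster cell")
    cnode = rc * ncols + cc
    graph = _raster_graph(raster, step_km)
    all_nodes = nodes + [cnode]
    dist = dijkstra(graph, directed=False, indices=all_nodes)
    m = len(nodes)
    d_pair = dist[:m][:, nodes]
    d_center = dist[m][nodes]
    if not np.isfinite(d_center).all():
        bad = sites.site_ids[int(np.flatnonzero(~np.isfinite(d_center))[0])]
        raise ValueError(f"site {bad} unreachable from the center")
    d_pair = 0.5 * (d_pair + d_pair.T)
    np.fill_diagonal(d_pair, 0.0)
    return DistanceSpec(d_center, d_pair, "routes")


def shared_path_covariance(dist: DistanceSpec) -> np.ndarray:
    """Raw shared-path covariance: off-diagonal
    ``rho_jk = max(0, (d_center[j] + d_center[k] - d_pair[j, k]) / 2)``,
    diagonal ``d_center[j]``. Exact on distances additive on a rooted tree."""
    d = dist.d_center
    rho = 0.5 * (d[:, None] + d[None, :] - dist.d_pair)
    rho = np.maximum(rho, 0.0)
    np.fill_diagonal(rho, d)
    return rho


def heuristic_covariance(dist: DistanceSpec) -> DispersalCovariance:
    """Shared-path covariance with PSD repair (negative eigenvalues clipped to
    zero) and scaling so the diagonal averages one."""
    if np.all(dist.d_center == 0):
        raise ValueError("degenerate region: all center distances are zero")
    raw = shared_path_covariance(dist)
    w, q = np.linalg.eigh(raw)
    w = np.maximum(w, 0.0)
    v = (q * w) @ q.T
    v = 0.5 * (v + v.T)
    scale = np.mean(np.diag(v))
    if scale <= 0:
        raise ValueError("degenerate region: zero mean diagonal after repair")
    return DispersalCovariance(v / scale, True, dist.scenario_label)


def read_distance_matrix(path) -> DistanceSpec:
    """Read a precomputed distance TSV: header ``site center <site ids...>``,
    one row per site with its center distance then the site-to-site row."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    if "site" not in df.columns or "center" not in df.columns:
        raise ValueError(f"{path}: need 'site' and 'center' columns")
    df = df.set_index("site")
    ids = list(df.index)
    d_center = df["center"].to_numpy(dtype=float)
    d_pair = df[ids].to_numpy(dtype=float)
    return DistanceSpec(d_center, d_pair, "matrix")


def write_distance_matrix(dist: DistanceSpec, site_ids, path, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("site\tcenter\t" + "\t".join(site_ids) + "\n")
        for j, sid in enumerate(site_ids):
            row = "\t".join("%.17g" % v for v in dist.d_pair[j])
            fh.write(f"{sid}\t{'%.17g' % dist.d_center[j]}\t{row}\n")
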