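"""Equal-area projection and home-range estimation.

Cleaned GPS fixes (WGS84 lon/lat) are projected with an Albers equal-area
conic so that polygon areas are meaningful, then summarised per animal with
two complementary estimators:

* **MCP** — minimum convex polygon of the ``percent``% of fixes nearest the
  arithmetic-mean range centre (the classical, outlier-peeled convex hull).
* **KUD** — kernel utilisation distribution: an isotropic bivariate Gaussian
  kernel density with the reference bandwidth ``href``, rasterised on a
  regular grid, from which volume isopleths (e.g. the 95% contour) are
  extracted as unions of grid cells.

Areas are computed in m² on the projected plane and reported in km².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.stats import chi2

from .errors import DegenerateInputError, InsufficientDataError, ParameterError

# Radius of the authalic sphere (m): spherical formulas on this radius
# preserve areas relative to the WGS84 ellipsoid to ~0.1%.
EARTH_RADIUS_AUTHALIC = 6_371_007.181

#: 0.95 quantile of the chi-square law with 2 df. For an isotropic bivariate
#: normal with per-axis SD sigma the 95% probability region is a disc of area
#: pi * sigma**2 * GAUSS95_QUANTILE — the analytic oracle used in tests.
GAUSS95_QUANTILE = float(chi2.ppf(0.95, 2))


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProjectionSpec:
    """Spherical Albers equal-area conic projection.

    Defaults bracket the Sarıkamış–Allahuekber study window
    (40.19–40.46° N, 42.39–42.76° E). False easting/northing are zero, so
    the point (central_meridian, latitude_of_origin) maps to (0, 0).
    """

    standard_parallels: tuple[float, float] = (40.25, 40.45)
    central_meridian: float = 42.58
    latitude_of_origin: float = 40.33
    radius: float = EARTH_RADIUS_AUTHALIC

    def _constants(self) -> tuple[float, float, float]:
        phi1, phi2 = np.radians(self.standard_parallels)
        n = 0.5 * (math.sin(phi1) + math.sin(phi2))
        if n == 0:
            raise ParameterError("standard parallels must not be symmetric about the equator")
        c = math.cos(phi1) ** 2 + 2.0 * n * math.sin(phi1)
        phi0 = math.radians(self.latitude_of_origin)
        rho0 = self.radius * math.sqrt(c - 2.0 * n * math.sin(phi0)) / n
        return n, c, rho0


def project(lon, lat, spec: ProjectionSpec = ProjectionSpec()) -> np.ndarray:
    """Forward Albers mapping of WGS84 lon/lat (degrees) to planar metres.

    Returns an (n, 2) array of (x, y).
    """
    n, c, rho0 = spec._constants()
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    lam0 = math.radians(spec.central_meridian)
    rho = spec.radius * np.sqrt(c - 2.0 * n * np.sin(phi)) / n
    theta = n * (lam - lam0)
    return np.column_stack((rho * np.sin(theta), rho0 - rho * np.cos(theta)))


def unproject(x, y, spec: ProjectionSpec = ProjectionSpec()) -> np.ndarray:
    """Inverse Albers mapping back to (lon, lat) degrees; (n, 2) array."""
    n, c, rho0 = spec._constants()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = np.hypot(x, rho0 - y)
    theta = np.arctan2(x, rho0 - y)
    phi = np.arcsin((c - (rho * n / spec.radius) ** 2) / (2.0 * n))
    lam = math.radians(spec.central_meridian) + theta / n
    return np.column_stack((np.degrees(lam), np.degrees(phi)))


def project_trajectory(traj: pd.DataFrame, spec: ProjectionSpec = ProjectionSpec()) -> np.ndarray:
    """Project a trajectory DataFrame's lon/lat columns to planar points."""
    return project(traj["lon"].to_numpy(), traj["lat"].to_numpy(), spec)


# ---------------------------------------------------------------------------
# Minimum convex polygon
# ---------------------------------------------------------------------------

def mcp(points: np.ndarray, percent: float = 95.0):
    """Minimum convex polygon home range.

    Retains the ``floor(percent/100 * n)`` points nearest (Euclidean) to the
    arithmetic-mean centre and returns ``(hull, area_km2)`` where *hull* is a
    shapely geometry. Collinear retained points yield a degenerate geometry
    with zero area.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("points must be an (n, 2) array")
    n = len(pts)
    if n < 5:
        raise InsufficientDataError(f"MCP requires >= 5 points, got {n}")
    if not 0 < percent <= 100:
        raise ParameterError("percent must be in (0, 100]")
    k = int(math.floor(percent / 100.0 * n))
    k = max(k, 1)
    center = pts.mean(axis=0)
    d = np.hypot(*(pts - center).T)
    keep = np.argsort(d, kind="stable")[:k]
    hull = shapely.MultiPoint(pts[keep]).convex_hull
    return hull, hull.area / 1e6


# ---------------------------------------------------------------------------
# Kernel utilisation distribution
# ---------------------------------------------------------------------------

def href_bandwidth(points: np.ndarray) -> float:
    """Reference (plug-in) bandwidth for a bivariate Gaussian kernel.

    h = sqrt(0.5 * (var(x) + var(y))) * n**(-1/6), variances with n-1.
    Raises :class:`DegenerateInputError` when all points coincide (h = 0).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        raise InsufficientDataError("href requires >= 2 points")
    s2 = 0.5 * (pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1))
    h = math.sqrt(s2) * n ** (-1.0 / 6.0)
    if h <= 0:
        raise DegenerateInputError("all points identical: reference bandwidth is zero")
    return h


@dataclass(frozen=True)
class GridSpec:
    """Regular raster grid: origin is the lower-left corner of cell (0, 0)."""

    cell_size: float = 250.0
    buffer: float = 10_000.0
    origin: tuple[float, float] = (0.0, 0.0)
    n_rows: int = 0
    n_cols: int = 0

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys): centre coordinates of columns and rows."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys


def make_grid(points: np.ndarray, cell_size: float = 250.0, buffer: float = 10_000.0) -> GridSpec:
    """Grid covering the point extent plus ``buffer`` on every side."""
    if cell_size <= 0 or buffer < 0:
        raise ParameterError("cell_size must be > 0 and buffer >= 0")
    pts = np.asarray(points, dtype=float)
    x0, y0 = pts.min(axis=0) - buffer
    x1, y1 = pts.max(axis=0) + buffer
    n_cols = int(math.ceil((x1 - x0) / cell_size))
    n_rows = int(math.ceil((y1 - y0) / cell_size))
    return GridSpec(cell_size, buffer, (float(x0), float(y0)), n_rows, n_cols)


@dataclass
class UDEstimate:
    """Gridded utilisation distribution (cell masses sum to 1)."""

    grid: GridSpec
    density: np.ndarray  # shape (n_rows, n_cols), row i <-> y index
    href: float
    total_mass: float  # raw kernel mass captured by the grid before renormalisation


def kud(points: np.ndarray, grid: GridSpec, h: float) -> UDEstimate:
    """Isotropic Gaussian kernel density on the grid's cell centres.

    The kernel sum is separable, so the field is a single matrix product of
    per-axis Gaussian factors. Cell masses are renormalised to sum to one;
    ``total_mass`` records the pre-normalisation mass (≈1 when the buffer
    extends ≥ 5 h beyond every point).
    """
    if h <= 0:
        raise ParameterError("bandwidth h must be > 0")
    pts = np.asarray(points, dtype=float)
    xs, ys = grid.cell_centers()
    gx = np.exp(-0.5 * ((xs[:, None] - pts[None, :, 0]) / h) ** 2)  # (n_cols, n)
    gy = np.exp(-0.5 * ((ys[:, None] - pts[None, :, 1]) / h) ** 2)  # (n_rows, n)
    scale = grid.cell_size**2 / (len(pts) * 2.0 * math.pi * h**2)
    density = scale * (gy @ gx.T)
    total = float(density.sum())
    if total <= 0:
        raise DegenerateInputError("kernel mass vanished on the grid")
    return UDEstimate(grid=grid, density=density / total, href=float(h), total_mass=total)


def ud_isopleth(ud: UDEstimate, level: float = 95.0, build_polygons: bool = True):
    """Volume isopleth of a normalised UD.

    Cells are ranked by density (descending; ties broken by row-major cell
    index so the contour is deterministic) and accumulated until the
    requested mass fraction is reached. Returns
    ``(polygons, area_km2, patch_count)`` where *polygons* is the dissolved
    union of the included cells (or ``None`` when ``build_polygons`` is
    false) and *patch_count* the number of 8-connected components.
    """
    if not 0 < level <= 100:
        raise ParameterError("level must be in (0, 100]")
    flat = ud.density.ravel()  # row-major
    order = np.argsort(-flat, kind="stable")
    cum = np.cumsum(flat[order])
    k = int(np.searchsorted(cum, level / 100.0 - 1e-12)) + 1
    k = min(k, int(np.count_nonzero(flat)))
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(ud.density.shape)
    _, patch_count = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    area_km2 = k * ud.grid.cell_size**2 / 1e6
    polygons = None
    if build_polygons:
        rows, cols = np.nonzero(mask)
        x0, y0 = ud.grid.origin
        c = ud.grid.cell_size
        boxes = shapely.box(x0 + cols * c, y0 + rows * c, x0 + (cols + 1) * c, y0 + (rows + 1) * c)
        polygons = shapely.union_all(boxes)
    return polygons, area_km2, int(patch_count)


# ---------------------------------------------------------------------------
# Per-animal driver
# ---------------------------------------------------------------------------

def tracking_days(timestamps: pd.Series) -> int:
    """Tracking duration in days: elapsed time, rounded up (minimum 1)."""
    span = (timestamps.max() - timestamps.min()) / pd.Timedelta(days=1)
    return max(int(math.ceil(span)), 1)


def estimate_home_ranges(
    trajectories: Mapping[str, pd.DataFrame],
    proj: ProjectionSpec = ProjectionSpec(),
    cell_size: float = 250.0,
    buffer: float = 10_000.0,
    percent: float = 95.0,
    min_fixes: int = 30,
    include_kud: bool = True,
):
    """Project each clean trajectory and estimate MCP and KUD ranges.

    Returns ``(table, artifacts)``: *table* has one row per animal
    (animal_id, mcp_km2, kud_km2, n_fixes, tracking_days, href_m,
    excluded_reason); *artifacts* maps animal_id to the projected points,
    hull, UD estimate and isopleth geometry for downstream diagnostics.
    Animals with fewer than ``min_fixes`` fixes are excluded with a reason.
    """
    rows = []
    artifacts: dict[str, dict] = {}
    for animal_id, traj in trajectories.items():
        n = len(traj)
        rec = {
            "animal_id": animal_id,
            "mcp_km2": np.nan,
            "kud_km2": np.nan,
            "n_fixes": n,
            "tracking_days": np.nan,
            "href_m": np.nan,
            "excluded_reason": None,
        }
        if n < min_fixes:
            rec["excluded_reason"] = "insufficient fixes"
            rows.append(rec)
            continue
        pts = project_trajectory(traj, proj)
        rec["tracking_days"] = tracking_days(traj["timestamp"])
        hull, mcp_area = mcp(pts, percent)
        rec["mcp_km2"] = mcp_area
        art = {"points": pts, "mcp_poly": hull, "ud": None, "kud_polys": None}
        if include_kud:
            try:
                h = href_bandwidth(pts)
                grid = make_grid(pts, cell_size, buffer)
                ud = kud(pts, grid, h)
                polys, kud_area, n_patches = ud_isopleth(ud, percent)
                rec.update(kud_km2=kud_area, href_m=h)
                art.update(ud=ud, kud_polys=polys, kud_patches=n_patches)
            except DegenerateInputError:
                rec["excluded_reason"] = "degenerate geometry for KUD"
        artifacts[animal_id] = art
        rows.append(rec)
    table = pd.DataFrame(rows)
    return table, artifacts
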