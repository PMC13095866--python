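"""Usability screening for kernel home-range estimates.

Five a priori criteria decide whether an individual's kernel utilisation
distribution reflects genuine space use rather than sampling artefacts:

(i)   sufficiency — at least ``min_fixes`` usable fixes spanning at least
      ``min_span_days`` days;
(ii)  temporal regularity — median fix interval <= ``max_median_interval_h``
      (inclusive) and no gap longer than ``max_gap_days`` days;
(iii) bandwidth stability — href within ``href_nn_ratio`` times the median
      nearest-neighbour distance among fixes;
(iv)  convergence — the KUD95-area-versus-cumulative-fix curve must plateau:
      absolute terminal slope < ``plateau_slope_pct``% per ``plateau_step``
      additional fixes;
(v)   shape — at most ``outside_mass_max`` of the kernel mass outside a
      ``hull_buffer_m`` buffer of the point cloud's convex hull, and at most
      ``max_patches`` disjoint patches in the 95% isopleth.

Failing individuals keep their MCP estimate but are excluded from
KUD-based summaries. Any criterion that raises on degenerate input is
recorded as failed (with the reason) rather than propagating the error.

A caution from synthetic experiments: with the reference bandwidth
``href = sigma * n**(-1/6)``, the ratio in criterion (iii) grows like
``n**(1/3)`` and exceeds 3 for essentially any point cloud with more than
~180 fixes, so under a 1-h fix schedule criteria (i) and (iii) cannot be
satisfied simultaneously. The band is applied exactly as configured;
see docs/methods.md for the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree

from .errors import BearHRError, InsufficientDataError
from .homerange import UDEstimate, href_bandwidth, kud, make_grid, ud_isopleth


@dataclass
class UsabilityConfig:
    min_fixes: int = 150
    min_span_days: float = 45.0
    max_median_interval_h: float = 6.0
    max_gap_days: float = 10.0
    href_nn_ratio: tuple[float, float] = (0.5, 3.0)
    plateau_slope_pct: float = 1.0
    plateau_step: int = 50
    outside_mass_max: float = 0.10
    hull_buffer_m: float = 1000.0
    max_patches: int = 5
    terminal_only: bool = True  # evaluate the plateau on the terminal segment only


@dataclass
class CriterionResult:
    passed: bool
    measured: dict = field(default_factory=dict)
    reason: str = ""


@dataclass
class UsabilityReport:
    animal_id: str
    sufficiency: CriterionResult
    regularity: CriterionResult
    bandwidth_stability: CriterionResult
    convergence: CriterionResult
    shape: CriterionResult

    @property
    def overall_pass(self) -> bool:
        return all(
            c.passed
            for c in (self.sufficiency, self.regularity, self.bandwidth_stability,
                      self.convergence, self.shape)
        )

    def to_dict(self) -> dict:
        d = {k: asdict(v) for k, v in self.__dict__.items() if isinstance(v, CriterionResult)}
        d["animal_id"] = self.animal_id
        d["overall_pass"] = self.overall_pass
        return d


def temporal_regularity(timestamps: pd.Series) -> tuple[float, float]:
    """(median successive interval in hours, maximum gap in days)."""
    ts = pd.Series(timestamps).sort_values()
    if len(ts) < 2:
        raise InsufficientDataError("temporal regularity needs >= 2 fixes")
    gaps_h = np.diff(ts.to_numpy()) / np.timedelta64(1, "h")
    return float(np.median(gaps_h)), float(gaps_h.max() / 24.0)


def bandwidth_stability(h: float, points: np.ndarray) -> float:
    """href divided by the median nearest-neighbour distance among fixes."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise InsufficientDataError("bandwidth stability needs >= 2 points")
    nn_dist, _ = cKDTree(pts).query(pts, k=2)
    med_nn = float(np.median(nn_dist[:, 1]))
    if med_nn == 0:
        raise BearHRError("median nearest-neighbour distance is zero (duplicated points)")
    return float(h) / med_nn


def convergence_curve(
    points: np.ndarray,
    cell_size: float = 250.0,
    buffer: float = 10_000.0,
    step: int = 50,
    level: float = 95.0,
) -> tuple[list[tuple[int, float]], float]:
    """KUD-area convergence over chronological prefixes of the track.

    Recomputes href and the KUD isopleth area on the first n fixes for
    n = step, 2*step, ..., N (N always included) and returns the curve with
    the terminal slope, in percent change per additional ``step`` fixes:
    ``100 * |A(N) - A(N - step)| / A(N - step) * (step / dn)``.
    """
    pts = np.asarray(points, dtype=float)
    n_total = len(pts)
    if n_total < 2 * step:
        raise InsufficientDataError(f"convergence needs >= {2 * step} fixes, got {n_total}")
    ns = list(range(step, n_total + 1, step))
    if ns[-1] != n_total:
        ns.append(n_total)
    curve = []
    for n in ns:
        sub = pts[:n]
        h = href_bandwidth(sub)
        ud = kud(sub, make_grid(sub, cell_size, buffer), h)
        _, area, _ = ud_isopleth(ud, level, build_polygons=False)
        curve.append((n, area))
    (n0, a0), (n1, a1) = curve[-2], curve[-1]
    if a0 <= 0:
        raise BearHRError("degenerate convergence curve: zero area")
    slope = 100.0 * abs(a1 - a0) / a0 * (step / (n1 - n0))
    return curve, float(slope)


def shape_diagnostics(
    ud: UDEstimate, points: np.ndarray, hull_buffer_m: float = 1000.0, level: float = 95.0
) -> tuple[float, int]:
    """(kernel mass outside the buffered convex hull, isopleth patch count).

    'Kernel mass' is the total UD mass whose cell centres fall outside the
    convex hull of the fixes dilated by ``hull_buffer_m``.
    """
    hull = shapely.MultiPoint(np.asarray(points, dtype=float)).convex_hull.buffer(hull_buffer_m)
    xs, ys = ud.grid.cell_centers()
    gx, gy = np.meshgrid(xs, ys)  # (n_rows, n_cols)
    centers = shapely.points(gx.ravel(), gy.ravel())
    inside = shapely.contains(hull, centers).reshape(ud.density.shape)
    outside_mass = float(ud.density[~inside].sum())
    _, _, patch_count = ud_isopleth(ud, level, build_polygons=False)
    return outside_mass, patch_count


def assess_usability(
    traj: pd.DataFrame,
    points: np.ndarray,
    ud: UDEstimate | None,
    cfg: UsabilityConfig = UsabilityConfig(),
    animal_id: str = "",
) -> UsabilityReport:
    """Evaluate all five criteria for one individual.

    All criteria are evaluated and reported even when an earlier one fails;
    a criterion that cannot be evaluated (degenerate input, missing UD)
    counts as failed, so ``overall_pass`` is fail-safe.
    """
    n = len(traj)

    def guarded(fn) -> CriterionResult:
        try:
            return fn()
        except BearHRError as exc:
            return CriterionResult(False, {}, reason=str(exc))

    def _sufficiency() -> CriterionResult:
        span_h = (traj["timestamp"].max() - traj["timestamp"].min()) / pd.Timedelta(hours=1)
        span_days = span_h / 24.0
        ok = n >= cfg.min_fixes and span_days >= cfg.min_span_days
        return CriterionResult(ok, {"n_fixes": n, "span_days": float(span_days)})

    def _regularity() -> CriterionResult:
        med_h, gap_d = temporal_regularity(traj["timestamp"])
        ok = med_h <= cfg.max_median_interval_h and gap_d <= cfg.max_gap_days
        return CriterionResult(ok, {"median_interval_h": med_h, "max_gap_days": gap_d})

    def _bandwidth() -> CriterionResult:
        if ud is None:
            return CriterionResult(False, {}, reason="no UD estimate")
        ratio = bandwidth_stability(ud.href, points)
        lo, hi = cfg.href_nn_ratio
        return CriterionResult(lo <= ratio <= hi, {"href_nn_ratio": ratio})

    def _convergence() -> CriterionResult:
        if ud is None:
            return CriterionResult(False, {}, reason="no UD estimate")
        _, slope = convergence_curve(
            points, ud.grid.cell_size, ud.grid.buffer, cfg.plateau_step
        )
        return CriterionResult(slope < cfg.plateau_slope_pct, {"terminal_slope_pct": slope})

    def _shape() -> CriterionResult:
        if ud is None:
            return CriterionResult(False, {}, reason="no UD estimate")
        outside, patches = shape_diagnostics(ud, points, cfg.hull_buffer_m)
        ok = outside <= cfg.outside_mass_max and patches <= cfg.max_patches
        return CriterionResult(ok, {"outside_mass_fraction": outside, "patch_count": patches})

    return UsabilityReport(
        animal_id=animal_id,
        sufficiency=guarded(_sufficiency),
        regularity=guarded(_regularity),
        bandwidth_stability=guarded(_bandwidth),
        convergence=guarded(_convergence),
        shape=guarded(_shape),
    )


def assess_all(
    clean_trajectories, artifacts, cfg: UsabilityConfig = UsabilityConfig()
) -> dict[str, UsabilityReport]:
    """Run :func:`assess_usability` for every animal with home-range artifacts."""
    out = {}
    for animal_id, art in artifacts.items():
        out[animal_id] = assess_usability(
            clean_trajectories[animal_id], art["points"], art.get("ud"), cfg, animal_id
        )
    return out
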