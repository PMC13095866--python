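"""Shared builders for test fixtures (tracks, defect fixtures, tables)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from bearhr.homerange import unproject
from bearhr.simulate import MovementParams, simulate_trajectory

T0 = pd.Timestamp("2023-05-01T00:00:00Z")


def planar_traj(xy: np.ndarray, times) -> pd.DataFrame:
    """Wrap planar points (m) into a clean trajectory DataFrame."""
    ll = unproject(xy[:, 0], xy[:, 1])
    return pd.DataFrame({"timestamp": times, "lon": ll[:, 0], "lat": ll[:, 1]})


def iid_gaussian_traj(n: int, sigma: float, times, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return planar_traj(rng.normal(0.0, sigma, (n, 2)), times)


def make_clean_track() -> pd.DataFrame:
    """The clean reference bear: 2000 1-h OU fixes, sigma = 2000 m."""
    return simulate_trajectory(MovementParams(), 1)


def make_fix149() -> pd.DataFrame:
    """149 fixes in 1-h bursts separated by 40-h pauses, spanning > 45 days."""
    hours = np.concatenate([[0.0], np.cumsum(np.tile([1.0] * 5 + [40.0], 30)[:148])])
    times = T0 + pd.to_timedelta(hours[:149], unit="h")
    return iid_gaussian_traj(149, 2000.0, times, 2)


def make_span44() -> pd.DataFrame:
    """300 fixes spanning exactly 44 days (regular ~3.5-h schedule)."""
    times = T0 + pd.to_timedelta(np.linspace(0, 44 * 24, 300), unit="h")
    return iid_gaussian_traj(300, 2000.0, times, 3)


def make_gap11() -> pd.DataFrame:
    """Clean reference track with an 11-day hole in the schedule."""
    traj = make_clean_track().copy()
    traj.loc[1000:, "timestamp"] = traj.loc[1000:, "timestamp"] + pd.Timedelta(days=11)
    return traj


def make_clusters6() -> pd.DataFrame:
    """Six tight clusters on a ring (16 km apart), 600 fixes over 46 days."""
    rng = np.random.default_rng(5)
    ang = np.arange(6) * np.pi / 3
    centers = 8000.0 * np.column_stack([np.cos(ang), np.sin(ang)])
    xy = np.repeat(centers, 100, axis=0) + rng.normal(0, 200.0, (600, 2))
    rng.shuffle(xy)
    times = T0 + pd.to_timedelta(np.linspace(0, 46 * 24, 600), unit="h")
    return planar_traj(xy, times)


def make_ratio4() -> pd.DataFrame:
    """300 near-independent fixes over 46 days: href/medNN measures ~4.0."""
    times = T0 + pd.to_timedelta(np.linspace(0, 46 * 24, 300), unit="h")
    return iid_gaussian_traj(300, 2000.0, times, 6)


USABILITY_FIXTURES = {
    "clean": (make_clean_track, None),
    "fix149": (make_fix149, "sufficiency"),
    "span44": (make_span44, "sufficiency"),
    "gap11": (make_gap11, "regularity"),
    "clusters6": (make_clusters6, "shape"),
    "ratio4": (make_ratio4, "bandwidth_stability"),
}


def usability_report(traj: pd.DataFrame):
    """Run a trajectory through home-range estimation + the usability screen."""
    from bearhr.homerange import estimate_home_ranges
    from bearhr.kud_qc import assess_all

    trajs = {"bear": traj}
    _, artifacts = estimate_home_ranges(trajs, min_fixes=5)
    return assess_all(trajs, artifacts)["bear"]


def make_sex_table(seed: int, n_m: int = 46, n_f: int = 23,
                   intercept: float = 3.68, effect: float = 0.65,
                   sd: float = 0.7) -> pd.DataFrame:
    """Direct draw from the log-scale sex model (no movement simulation)."""
    rng = np.random.default_rng(seed)
    sex = np.array(["M"] * n_m + ["F"] * n_f)
    log_mcp = intercept + effect * (sex == "M") + rng.normal(0.0, sd, n_m + n_f)
    return pd.DataFrame(
        {
            "animal_id": [f"B{i:03d}" for i in range(n_m + n_f)],
            "sex": sex,
            "log_mcp": log_mcp,
            "mcp_km2": np.exp(log_mcp),
        }
    )
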