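"""GPS fix-quality filtering.

Implements the explicit filter cascade used to retain only high-quality
fixes before home-range estimation, applied per animal and in this order:

1. fixes lacking coordinates (or timestamps, handled at parse) are removed;
2. only allowed fix types are kept (3D and high-quality 2D by default);
3. HDOP above the threshold — strictly ``> 5`` — or missing is removed;
4. altitude clearly outside the plausible elevation range is removed
   (fixes with altitude simply missing are kept);
5. coordinate jumps > 1 km within <= 5 min drop the later fix of the pair;
6. implied speeds > 10 km/h over intervals >= 30 min drop the later fix;
7. steps longer than ``step_multiplier`` x the individual's 99th-percentile
   step length drop the later fix.

Rules 5–7 iterate — steps are recomputed after each pass — until no fix is
removed, which makes the filter idempotent. Within a pass, a step departing
from a fix already flagged in that pass is ignored (it will be re-evaluated
against the new neighbour on the next pass); this avoids cascading removals
of clean fixes adjacent to a single outlier. Distances are great-circle
(haversine) on the raw WGS84 coordinates, since QC precedes projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

EARTH_RADIUS_MEAN = 6_371_000.0  # m

RULES = ("missing_coordinate", "fix_type", "hdop", "altitude", "jump", "speed", "step_length")


@dataclass
class QCConfig:
    hdop_max: float = 5.0
    speed_max: float = 10.0          # km/h
    speed_min_interval: float = 30.0  # min; speed rule applies at intervals >= this
    step_pctl: float = 99.0
    step_multiplier: float = 2.5      # admissible range [2, 3]
    jump_dist: float = 1.0            # km
    jump_max_interval: float = 5.0    # min; jump rule applies at intervals <= this
    altitude_range: tuple[float, float] = (1000.0, 3500.0)
    allowed_fix_types: frozenset = frozenset({"3D", "2D-high"})

    def validate(self) -> None:
        if not 2.0 <= self.step_multiplier <= 3.0:
            raise FormatError("step_multiplier must lie in [2, 3]")


@dataclass
class QCReport:
    """Per-animal filter accounting: removed + retained == input size."""

    n_input: int
    n_retained: int
    counts: dict = field(default_factory=dict)  # first-reason count per rule
    reasons: pd.Series | None = None            # reason code per removed fix

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance (m) on the mean-radius sphere."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_MEAN * np.arcsin(np.sqrt(a))


def parse_fixes(source) -> tuple[dict[str, pd.DataFrame], dict]:
    """Read a fixes CSV (or DataFrame) into per-animal trajectories.

    Trajectories are sorted by timestamp; duplicate (animal, timestamp) rows
    collapse to the first; rows with unparseable timestamps are dropped and
    counted. Rows with missing coordinates are *retained* here — removing
    them is the first filter rule, so the QC report can account for them.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    for col in ("AnimalID", "timestamp", "lon", "lat", "fix_type", "hdop", "altitude_m"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col!r}")
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    n_bad_ts = int(ts.isna().sum())
    df = df.loc[~ts.isna()].assign(timestamp=ts[~ts.isna()])
    for col in ("lon", "lat", "hdop", "altitude_m"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.sort_values(["AnimalID", "timestamp"], kind="stable")
    n_before = len(df)
    df = df.drop_duplicates(subset=["AnimalID", "timestamp"], keep="first")
    report = {"n_dropped_timestamp": n_bad_ts, "n_duplicates": n_before - len(df)}
    trajectories = {
        str(aid): g.drop(columns=["AnimalID"]).reset_index(drop=True)
        for aid, g in df.groupby("AnimalID", sort=True)
    }
    return trajectories, report


def step_metrics(traj: pd.DataFrame) -> pd.DataFrame:
    """Step length (m), interval (min) and implied speed (km/h) between
    consecutive fixes that carry coordinates. Empty for < 2 usable fixes."""
    ok = traj.dropna(subset=["lon", "lat"])
    if len(ok) < 2:
        return pd.DataFrame(columns=["from_idx", "to_idx", "step_m", "interval_min", "speed_kmh"])
    lon = ok["lon"].to_numpy()
    lat = ok["lat"].to_numpy()
    step = haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])
    dt_min = np.diff(ok["timestamp"].to_numpy()) / np.timedelta64(1, "m")
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = np.where(dt_min > 0, (step / 1000.0) / (dt_min / 60.0), np.inf)
    speed = np.where(step == 0, 0.0, speed)
    return pd.DataFrame(
        {
            "from_idx": ok.index[:-1],
            "to_idx": ok.index[1:],
            "step_m": step,
            "interval_min": dt_min,
            "speed_kmh": speed,
        }
    )


def _movement_flags(traj: pd.DataFrame, cfg: QCConfig) -> dict[int, str]:
    """One pass of the movement rules; returns {row index: rule} to drop."""
    steps = step_metrics(traj)
    if steps.empty:
        return {}
    pctl = np.percentile(steps["step_m"], cfg.step_pctl)  # linear interpolation
    jump = (steps["step_m"] > cfg.jump_dist * 1000.0) & (
        steps["interval_min"] <= cfg.jump_max_interval
    )
    speed = (steps["speed_kmh"] > cfg.speed_max) & (
        steps["interval_min"] >= cfg.speed_min_interval
    )
    too_long = steps["step_m"] > cfg.step_multiplier * pctl
    flagged: dict[int, str] = {}
    for j in np.nonzero((jump | speed | too_long).to_numpy())[0]:
        row = steps.iloc[j]
        if row["from_idx"] in flagged:
            continue  # departing fix already flagged this pass; re-check next pass
        rule = "jump" if jump.iloc[j] else ("speed" if speed.iloc[j] else "step_length")
        flagged[row["to_idx"]] = rule
    return flagged


def filter_fixes(traj: pd.DataFrame, cfg: QCConfig = QCConfig()) -> tuple[pd.DataFrame, QCReport]:
    """Apply the full filter cascade to one parsed trajectory."""
    cfg.validate()
    n_input = len(traj)
    reasons = pd.Series("", index=traj.index, dtype=object)

    def mark(mask: pd.Series, rule: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = rule

    mark(traj["lon"].isna() | traj["lat"].isna(), "missing_coordinate")
    mark(~traj["fix_type"].isin(cfg.allowed_fix_types), "fix_type")
    mark(traj["hdop"].isna() | (traj["hdop"] > cfg.hdop_max), "hdop")
    lo, hi = cfg.altitude_range
    alt = traj["altitude_m"]
    mark(alt.notna() & ((alt < lo) | (alt > hi)), "altitude")

    current = traj.loc[reasons == ""]
    while True:
        flagged = _movement_flags(current, cfg)
        if not flagged:
            break
        for idx, rule in flagged.items():
            reasons[idx] = rule
        current = current.drop(index=list(flagged))

    counts = {rule: int((reasons == rule).sum()) for rule in RULES}
    clean = current.reset_index(drop=True)
    report = QCReport(
        n_input=n_input,
        n_retained=len(clean),
        counts=counts,
        reasons=reasons[reasons != ""],
    )
    return clean, report


def qc_trajectories(
    trajectories: Mapping[str, pd.DataFrame], cfg: QCConfig = QCConfig()
) -> tuple[dict[str, pd.DataFrame], dict[str, QCReport]]:
    """Filter every animal; returns (clean trajectories, per-animal reports)."""
    clean, reports = {}, {}
    for animal_id, traj in trajectories.items():
        clean[animal_id], reports[animal_id] = filter_fixes(traj, cfg)
    return clean, reports
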