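"""From raw arena trajectories to one exploratory speed per individual.

Image-based tracking of an animal in a circular arena yields a time-ordered
series of planar positions (x, y in mm, timestamps in seconds at a nominal
38 frames/s).  Tracking of an inactive animal still records tiny spurious
position changes, so per-frame speeds are filtered with a hysteresis rule
before aggregation: a movement bout opens when speed first reaches the start
threshold (0.6 mm/s) and closes just before the first later frame whose
speed drops below the stop threshold (0.3 mm/s).  Only frames inside bouts
contribute to the exploratory speed, computed as total within-bout distance
over total within-bout duration and reported in m/s.

Bout indices refer to the speed series (one entry per consecutive frame
pair), not to trajectory frames; the first frame carries no speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "SpeedSeries",
    "MovementBout",
    "FilterConfig",
    "IndividualRecord",
    "compute_speeds",
    "segment_bouts",
    "exploratory_speed",
    "process_trajectory",
    "read_trajectory_csv",
    "read_metadata_csv",
    "build_records",
]

NOMINAL_FRAME_RATE = 38.0  # pictures per second, camera metadata


@dataclass
class Trajectory:
    """One individual's tracked path: strictly increasing times, mm coords."""

    individual_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float = NOMINAL_FRAME_RATE

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal length")
        if self.t.size < 1:
            raise ValueError("trajectory must contain at least one point")
        for name, arr in (("t", self.t), ("x", self.x), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise ValueError(f"non-finite {name} at index {bad}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            bad = int(np.flatnonzero(dt <= 0)[0])
            raise ValueError(
                f"timestamps not strictly increasing at index {bad + 1} "
                f"(t={self.t[bad + 1]!r} after t={self.t[bad]!r})")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class SpeedSeries:
    """Per-frame-pair speeds (mm/s) with midpoint times and step durations."""

    t_mid: np.ndarray
    speed: np.ndarray
    dt: np.ndarray

    def __len__(self) -> int:
        return self.speed.size


@dataclass(frozen=True)
class MovementBout:
    """A contiguous run of active-movement speed-series indices.

    ``start_index`` inclusive, ``stop_index`` exclusive, both indexing the
    speed series.  ``duration`` (s) and ``distance`` (mm) are accumulated
    over the frame pairs inside the bout.
    """

    start_index: int
    stop_index: int
    duration: float
    distance: float

    def __post_init__(self):
        if not self.start_index < self.stop_index:
            raise ValueError("bout must contain at least one frame pair")


@dataclass(frozen=True)
class FilterConfig:
    """Hysteresis speed thresholds (mm/s) for bout segmentation."""

    v_start: float = 0.6
    v_stop: float = 0.3

    def __post_init__(self):
        if not (0 < self.v_stop <= self.v_start):
            raise ValueError(
                f"need 0 < v_stop <= v_start, got v_start={self.v_start}, "
                f"v_stop={self.v_stop}")


@dataclass(frozen=True)
class IndividualRecord:
    """One row of the analysis table: who, how heavy, how warm, how fast."""

    individual_id: str
    species: str
    mass_mg: float
    temperature_C: float
    speed_m_s: float  # NaN when no movement bout was observed
    habitat_group: str | None = None


def compute_speeds(traj: Trajectory) -> SpeedSeries:
    """Per-frame speeds: Euclidean displacement over time step, in mm/s.

    A trajectory with fewer than two points yields an empty series.
    """
    if len(traj) < 2:
        e = np.empty(0)
        return SpeedSeries(t_mid=e.copy(), speed=e.copy(), dt=e.copy())
    dt = np.diff(traj.t)
    if np.any(dt <= 0):
        bad = int(np.flatnonzero(dt <= 0)[0])
        raise ValueError(f"duplicate or decreasing timestamp at index "
                         f"{bad + 1}")
    dist = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return SpeedSeries(
        t_mid=0.5 * (traj.t[:-1] + traj.t[1:]),
        speed=dist / dt,
        dt=dt,
    )


def smooth_speeds(speeds: SpeedSeries, window: int) -> SpeedSeries:
    """Centered moving-average smoothing of the speed values (optional).

    Off by default in the pipeline; provided for users whose tracking noise
    survives the hysteresis filter.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1 or len(speeds) == 0:
        return speeds
    s = pd.Series(speeds.speed).rolling(
        window, center=True, min_periods=1).mean().to_numpy()
    return SpeedSeries(t_mid=speeds.t_mid, speed=s, dt=speeds.dt)


def segment_bouts(speeds: SpeedSeries, cfg: FilterConfig = FilterConfig()
                  ) -> list[MovementBout]:
    """Hysteresis segmentation of the speed series into movement bouts.

    A bout opens at the first frame with speed >= ``v_start`` while no bout
    is open, and closes immediately before the first subsequent frame with
    speed < ``v_stop``; a bout still open at the end of the series closes at
    the end.  No minimum bout duration is imposed.
    """
    v = np.asarray(speeds.speed, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v < 0):
        raise ValueError("speeds must be finite and non-negative")
    bouts: list[MovementBout] = []
    open_start: int | None = None
    for i, s in enumerate(v):
        if open_start is None:
            if s >= cfg.v_start:
                open_start = i
        elif s < cfg.v_stop:
            bouts.append(_make_bout(speeds, open_start, i))
            open_start = None
    if open_start is not None:
        bouts.append(_make_bout(speeds, open_start, len(v)))
    return bouts


def _make_bout(speeds: SpeedSeries, start: int, stop: int) -> MovementBout:
    dt = speeds.dt[start:stop]
    return MovementBout(
        start_index=start,
        stop_index=stop,
        duration=float(dt.sum()),
        distance=float((speeds.speed[start:stop] * dt).sum()),
    )


def exploratory_speed(traj: Trajectory, bouts: list[MovementBout]) -> float:
    """Total within-bout distance over total within-bout time, in m/s.

    Returns NaN (flagged missing, never zero) when the animal produced no
    movement bout.
    """
    if not bouts:
        return float("nan")
    distance = sum(b.distance for b in bouts)   # mm
    duration = sum(b.duration for b in bouts)   # s
    return distance / duration / 1000.0


def process_trajectory(traj: Trajectory,
                       cfg: FilterConfig = FilterConfig(),
                       trim: tuple[float, float] | None = None,
                       smooth_window: int | None = None) -> float:
    """Full single-individual pipeline: speeds -> bouts -> exploratory speed.

    ``trim=(t0, t1)`` restricts the trajectory to a recording window in
    seconds before filtering (off by default); ``smooth_window`` applies a
    centered moving average to the speeds before thresholding (off by
    default — thresholds act on raw per-frame speeds).
    """
    if trim is not None:
        t0, t1 = trim
        keep = (traj.t >= t0) & (traj.t <= t1)
        if keep.sum() < 2:
            return float("nan")
        traj = Trajectory(traj.individual_id, traj.t[keep], traj.x[keep],
                          traj.y[keep], frame_rate=traj.frame_rate)
    speeds = compute_speeds(traj)
    if len(speeds) == 0:
        return float("nan")
    seg_input = speeds
    if smooth_window is not None:
        seg_input = smooth_speeds(speeds, smooth_window)
    bouts = segment_bouts(seg_input, cfg)
    return exploratory_speed(traj, bouts)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trajectory_csv(path) -> list[Trajectory]:
    """Read trajectories from a CSV with columns ``id,t,x,y``.

    ``t`` in seconds, ``x``/``y`` in mm.  Rows are grouped by ``id`` and
    sorted by time within each individual.
    """
    df = pd.read_csv(path)
    needed = {"id", "t", "x", "y"}
    if not needed <= set(df.columns):
        raise ValueError(
            f"trajectory CSV must have columns {sorted(needed)}, "
            f"got {list(df.columns)}")
    out = []
    for ind, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("t")
        out.append(Trajectory(str(ind), sub["t"].to_numpy(),
                              sub["x"].to_numpy(), sub["y"].to_numpy()))
    return out


def read_metadata_csv(path) -> pd.DataFrame:
    """Read the individual-metadata CSV: id,species,habitat_group,mass_mg,temperature_C."""
    df = pd.read_csv(path)
    needed = {"id", "species", "mass_mg", "temperature_C"}
    if not needed <= set(df.columns):
        raise ValueError(
            f"metadata CSV must have columns {sorted(needed)}, "
            f"got {list(df.columns)}")
    if "habitat_group" not in df.columns:
        df["habitat_group"] = None
    if (df["mass_mg"] <= 0).any():
        raise ValueError("metadata contains non-positive body masses")
    return df


def build_records(trajectories: list[Trajectory], metadata: pd.DataFrame,
                  cfg: FilterConfig = FilterConfig(),
                  trim: tuple[float, float] | None = None,
                  smooth_window: int | None = None) -> pd.DataFrame:
    """Join processed trajectories with metadata into the analysis table.

    Returns one row per individual with columns ``individual_id, species,
    habitat_group, mass_mg, temperature_C, speed_m_s``; individuals without
    any movement bout carry NaN speed.
    """
    meta = metadata.set_index(metadata["id"].astype(str))
    rows = []
    for traj in trajectories:
        if traj.individual_id not in meta.index:
            raise ValueError(
                f"no metadata for individual '{traj.individual_id}'")
        m = meta.loc[traj.individual_id]
        rows.append({
            "individual_id": traj.individual_id,
            "species": m["species"],
            "habitat_group": m.get("habitat_group"),
            "mass_mg": float(m["mass_mg"]),
            "temperature_C": float(m["temperature_C"]),
            "speed_m_s": process_trajectory(traj, cfg, trim=trim,
                                            smooth_window=smooth_window),
        })
    return pd.DataFrame(rows)
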