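"""Activity endpoints: distance traveled, swim speed, time in motion,
and tank exploration.

Instantaneous speed uses backward differences on the common frame grid
with no smoothing.  Steps that span an excluded frame are omitted; the
"valid duration" used for rates is the tracked frame count divided by
the frame rate.  Exploration rasterizes the arena into square cells
(10 mm by default) and reports both mm^2 visited and percent of arena.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    CalibrationInfo,
    ConfigError,
    DataError,
    EndpointTable,
    GroupRecording,
    Trajectory,
)

__all__ = [
    "ActivityConfig",
    "distance_traveled",
    "swim_speed",
    "time_in_motion",
    "exploration_area",
    "activity_endpoints",
]


@dataclass(frozen=True)
class ActivityConfig:
    """Thresholds the activity endpoints require.

    ``motion_speed_threshold_mm_s``: a frame counts as "in motion" when
    its backward-difference speed exceeds this (5 mm/s default, about
    half a body length per second for small wild fish; 0 makes every
    moving frame count).  ``exploration_cell_mm``: side of the square
    exploration grid cell (10 mm default).
    """

    motion_speed_threshold_mm_s: float = 5.0
    exploration_cell_mm: float = 10.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.motion_speed_threshold_mm_s) or self.motion_speed_threshold_mm_s < 0:
            raise ConfigError("motion_speed_threshold_mm_s must be finite and non-negative")
        if not self.exploration_cell_mm > 0:
            raise ConfigError("exploration_cell_mm must be strictly positive")

    def validate_against(self, cal: CalibrationInfo) -> None:
        if self.exploration_cell_mm >= min(cal.arena_width_mm, cal.arena_height_mm):
            raise ConfigError("exploration cell must be smaller than both arena dimensions")


def _step_lengths_mm(traj: Trajectory, cal: CalibrationInfo) -> np.ndarray:
    """Lengths (mm) of steps between consecutive frames; NaN where either
    endpoint frame is excluded."""
    xy = traj.positions_px / cal.px_per_mm
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return steps  # NaN propagates from excluded frames


def distance_traveled(traj: Trajectory, cal: CalibrationInfo) -> float:
    """Total mm traversed over consecutive valid frame pairs."""
    if not traj.valid_mask.any():
        raise DataError(f"fish {traj.fish_id}: all frames excluded")
    steps = _step_lengths_mm(traj, cal)
    return float(np.nansum(steps))


def valid_duration_s(traj: Trajectory, cal: CalibrationInfo) -> float:
    """Tracked duration: number of valid frames over the frame rate."""
    return float(traj.valid_mask.sum() / cal.frame_rate)


def swim_speed(traj: Trajectory, cal: CalibrationInfo) -> float:
    """Distance traveled divided by the valid observed duration, mm/s."""
    dur = valid_duration_s(traj, cal)
    if dur <= 0:
        raise DataError(f"fish {traj.fish_id}: zero valid duration")
    return distance_traveled(traj, cal) / dur


def time_in_motion(traj: Trajectory, cal: CalibrationInfo, cfg: ActivityConfig | None = None) -> float:
    """Seconds whose backward-difference speed exceeds the motion
    threshold."""
    cfg = cfg or ActivityConfig()
    steps = _step_lengths_mm(traj, cal)
    speeds = steps * cal.frame_rate  # mm/s per frame transition
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons
        moving = np.nansum(speeds > cfg.motion_speed_threshold_mm_s)
    return float(moving / cal.frame_rate)


def exploration_area(
    traj: Trajectory, cal: CalibrationInfo, cfg: ActivityConfig | None = None
) -> tuple[float, float]:
    """Arena area visited: (mm^2, percent of arena).

    The arena is partitioned into ``exploration_cell_mm`` square cells
    (edge cells truncated at the walls); a cell counts as visited when it
    contains at least one valid position.  Visited area is the cell count
    times the full cell area, capped at the arena area.  Positions
    outside the arena raise a warning and are clamped to the boundary
    cell.
    """
    cfg = cfg or ActivityConfig()
    cfg.validate_against(cal)
    cell = cfg.exploration_cell_mm
    nx = int(np.ceil(cal.arena_width_mm / cell))
    ny = int(np.ceil(cal.arena_height_mm / cell))
    xy = traj.positions_px[traj.valid_mask] / cal.px_per_mm
    if len(xy) == 0:
        raise DataError(f"fish {traj.fish_id}: all frames excluded")
    oob = (
        (xy[:, 0] < 0) | (xy[:, 0] > cal.arena_width_mm)
        | (xy[:, 1] < 0) | (xy[:, 1] > cal.arena_height_mm)
    )
    if oob.any():
        warnings.warn(
            f"fish {traj.fish_id}: {int(oob.sum())} positions outside the arena; "
            "clamped to boundary cells",
            stacklevel=2,
        )
    ix = np.clip((xy[:, 0] // cell).astype(int), 0, nx - 1)
    iy = np.clip((xy[:, 1] // cell).astype(int), 0, ny - 1)
    n_cells = len(np.unique(ix * ny + iy))
    area = min(n_cells * cell * cell, cal.arena_area_mm2)
    return float(area), float(area / cal.arena_area_mm2 * 100.0)


def activity_endpoints(group: GroupRecording, cfg: ActivityConfig | None = None) -> EndpointTable:
    """All four activity endpoints per fish as a tidy table."""
    cfg = cfg or ActivityConfig()
    rows = []
    for tr in group.trajectories:
        area, pct = exploration_area(tr, group.calibration, cfg)
        rows.append(
            {
                "site": group.site,
                "tank_id": group.tank_id,
                "fish_id": tr.fish_id,
                "distance_traveled_mm": distance_traveled(tr, group.calibration),
                "swim_speed_mm_s": swim_speed(tr, group.calibration),
                "time_in_motion_s": time_in_motion(tr, group.calibration, cfg),
                "exploration_mm2": area,
                "exploration_pct": pct,
            }
        )
    units = {
        "distance_traveled_mm": "mm",
        "swim_speed_mm_s": "mm/s",
        "time_in_motion_s": "s",
        "exploration_mm2": "mm^2",
        "exploration_pct": "%",
    }
    return EndpointTable(data=pd.DataFrame(rows), units=units, level="fish")
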