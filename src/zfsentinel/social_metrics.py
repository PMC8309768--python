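"""Shoaling cohesion endpoints.

Three per-fish social measures over a group recording:

* inter-individual distance (IID): time-averaged mean Euclidean distance
  to all other group members, mm;
* time in proximity: seconds spent with at least one neighbour within a
  two-body-length threshold (1000 px by default, following the field
  standardization; an mm threshold can be used instead);
* nearest-neighbour distance (NND): time-averaged distance to the
  closest group member, mm.

Frames excluded by the gap-handling rule (any fish missing) are dropped
from both numerator and denominator, so all three measures are averages
over valid frames only.  Per-fish values are collapsed to tank means for
between-site statistics, the tank being the independent unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ConfigError, DataError, EndpointTable, GroupRecording, UnitError

__all__ = [
    "ProximityConfig",
    "interindividual_distance",
    "time_in_proximity",
    "nearest_neighbor_distance",
    "social_endpoints",
    "collapse_to_tank_means",
]


@dataclass(frozen=True)
class ProximityConfig:
    """Proximity threshold: 1000 px by default (two body lengths in the
    original optics), or an mm-denominated alternative for other setups."""

    threshold_px: float = 1000.0
    use_mm: bool = False
    threshold_mm: float | None = None

    def __post_init__(self) -> None:
        if self.use_mm:
            if self.threshold_mm is None or self.threshold_mm <= 0:
                raise ConfigError("use_mm set but threshold_mm not strictly positive")
        elif not self.threshold_px > 0:
            raise ConfigError(f"threshold_px must be strictly positive, got {self.threshold_px}")

    def threshold_in_px(self, px_per_mm: float) -> float:
        return self.threshold_mm * px_per_mm if self.use_mm else self.threshold_px


def _pairwise_distances(group: GroupRecording) -> tuple[np.ndarray, np.ndarray]:
    """Distance matrix per frame (n_fish, n_fish, n_frames) in px, plus
    the mask of frames where every fish has a valid position."""
    if group.n_fish < 2:
        raise DataError(f"tank {group.tank_id}: social metrics need at least 2 fish")
    P = group.positions_array()  # (F, T, 2)
    valid = np.all(np.isfinite(P), axis=(0, 2))  # frame valid iff all fish present
    diff = P[:, None, :, :] - P[None, :, :, :]
    d = np.sqrt(np.sum(diff**2, axis=-1))  # (F, F, T)
    return d, valid


def interindividual_distance(group: GroupRecording) -> pd.Series:
    """Per-fish mean (over valid frames) of the mean distance to all
    other group members, in mm."""
    d, valid = _pairwise_distances(group)
    if not valid.any():
        raise DataError(f"tank {group.tank_id}: no frames where all fish are tracked")
    F = group.n_fish
    off = ~np.eye(F, dtype=bool)
    # mean over j != i, then over valid frames
    per_frame = d[:, :, valid][off].reshape(F, F - 1, -1).mean(axis=1)
    mm = per_frame.mean(axis=1) / group.calibration.px_per_mm
    return pd.Series(mm, index=group.fish_ids, name="interindividual_distance_mm")


def nearest_neighbor_distance(group: GroupRecording) -> pd.Series:
    """Per-fish mean (over valid frames) distance to the closest group
    member, in mm."""
    d, valid = _pairwise_distances(group)
    if not valid.any():
        raise DataError(f"tank {group.tank_id}: no frames where all fish are tracked")
    F = group.n_fish
    dv = d[:, :, valid].copy()
    dv[np.eye(F, dtype=bool)] = np.inf
    mm = dv.min(axis=1).mean(axis=1) / group.calibration.px_per_mm
    return pd.Series(mm, index=group.fish_ids, name="nearest_neighbor_distance_mm")


def time_in_proximity(group: GroupRecording, cfg: ProximityConfig | None = None) -> pd.Series:
    """Per-fish seconds with any neighbour within the threshold
    (inclusive comparison), counted over valid frames."""
    cfg = cfg or ProximityConfig()
    thr = cfg.threshold_in_px(group.calibration.px_per_mm)
    d, valid = _pairwise_distances(group)
    F = group.n_fish
    dv = d[:, :, valid].copy()
    dv[np.eye(F, dtype=bool)] = np.inf
    n_close = np.sum(dv.min(axis=1) <= thr, axis=1)
    seconds = n_close / group.calibration.frame_rate
    seconds = np.minimum(seconds, group.sample_duration_s)
    return pd.Series(seconds, index=group.fish_ids, name="time_in_proximity_s")


def social_endpoints(group: GroupRecording, cfg: ProximityConfig | None = None) -> EndpointTable:
    """All three social endpoints per fish as a tidy table.

    ``proximity_fraction`` reports time in proximity as a fraction of the
    valid (tracked) duration, so tanks with excluded frames remain
    comparable.
    """
    iid = interindividual_distance(group)
    nnd = nearest_neighbor_distance(group)
    tip = time_in_proximity(group, cfg)
    _, valid = _pairwise_distances(group)
    valid_s = valid.sum() / group.calibration.frame_rate
    data = pd.DataFrame(
        {
            "site": group.site,
            "tank_id": group.tank_id,
            "fish_id": iid.index,
            "interindividual_distance_mm": iid.values,
            "nearest_neighbor_distance_mm": nnd.values,
            "time_in_proximity_s": tip.values,
            "proximity_fraction": tip.values / valid_s if valid_s > 0 else np.nan,
        }
    )
    units = {
        "interindividual_distance_mm": "mm",
        "nearest_neighbor_distance_mm": "mm",
        "time_in_proximity_s": "s",
        "proximity_fraction": "",
    }
    return EndpointTable(data=data, units=units, level="fish")


def collapse_to_tank_means(per_fish: EndpointTable) -> EndpointTable:
    """Collapse a fish-level table to tank means (the independent unit
    for between-site tests); adds an ``n_per_site`` tank count column."""
    if per_fish.level != "fish":
        raise DataError("collapse_to_tank_means expects a fish-level table")
    cols = per_fish.endpoint_columns
    for c in cols:
        if not pd.api.types.is_numeric_dtype(per_fish.data[c]):
            raise UnitError(f"endpoint column {c!r} is not numeric")
    g = per_fish.data.groupby(["site", "tank_id"], sort=True)
    means = g[cols].mean().reset_index()
    tanks_per_site = means.groupby("site")["tank_id"].transform("count")
    means["n_per_site"] = tanks_per_site.astype(float)
    units = dict(per_fish.units)
    units["n_per_site"] = ""
    return EndpointTable(data=means, units=units, level="tank")
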