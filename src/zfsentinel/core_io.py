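"""Domain types, file I/O, calibration, and tracking-quality gates.

The behavioral half of the pipeline consumes per-frame 2-D fish positions
exported by video-tracking software (one row per frame per fish, pixel
coordinates); the morphometric half consumes 7-landmark configurations
digitized on dorsal photographs, stored in the TPS format written by
tpsDIG.  Everything downstream works in millimetres, so calibration
(pixels per mm, frame rate, arena size) is attached at read time.

Missing detections are an unavoidable feature of field video tracking.
Gaps of at most ``max_gap_frames`` consecutive frames are filled by
linear interpolation; longer gaps are left as NaN and every metric
excludes those frames.  The fraction of frames with an actual detection
is recorded *before* any interpolation and drives the tracking-accuracy
quality gate (a tank is analyzable only if every fish was tracked in at
least 80% of frames by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "DataError",
    "UnitError",
    "ConfigError",
    "CalibrationInfo",
    "Trajectory",
    "GroupRecording",
    "LandmarkSet",
    "EndpointTable",
    "LANDMARK_NAMES",
    "read_trajectory_table",
    "write_trajectory_table",
    "qc_tracking_accuracy",
    "read_tps",
    "write_tps",
    "write_endpoint_table",
    "read_endpoint_table",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class DataError(ValueError):
    """Structurally valid input that violates a data contract."""


class UnitError(ValueError):
    """Units are missing or inconsistent."""


class ConfigError(ValueError):
    """Invalid configuration value."""


#: Anatomical meaning of the seven landmarks, in file order (1-based).
LANDMARK_NAMES = (
    "mouth",
    "posterior dorsal skull",
    "anterior dorsal fin",
    "caudal fin",
    "anterior anal fin",
    "ventral surface",
    "ventral anterior skull",
)

N_LANDMARKS = 7


@dataclass(frozen=True)
class CalibrationInfo:
    """Pixel-to-mm calibration plus arena geometry.

    Defaults describe a 30.8 cm x 34 cm test tank filmed from above.
    """

    px_per_mm: float
    frame_rate: float
    arena_width_mm: float = 308.0
    arena_height_mm: float = 340.0

    def __post_init__(self) -> None:
        for name in ("px_per_mm", "frame_rate", "arena_width_mm", "arena_height_mm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigError(f"CalibrationInfo.{name} must be strictly positive, got {v!r}")

    def px_to_mm(self, px: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(px, dtype=float) / self.px_per_mm if np.ndim(px) else px / self.px_per_mm

    @property
    def arena_area_mm2(self) -> float:
        return self.arena_width_mm * self.arena_height_mm


@dataclass
class Trajectory:
    """One fish's positions on a common frame grid.

    ``positions_px`` has shape (n_frames, 2); frames excluded by the
    gap-handling rule hold NaN.  ``detection_fraction`` is the fraction
    of grid frames with an actual (pre-interpolation) detection.
    """

    fish_id: str
    times_s: np.ndarray
    positions_px: np.ndarray
    detection_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        if self.times_s.ndim != 1 or len(self.times_s) < 2:
            raise DataError(f"fish {self.fish_id}: need at least 2 frames")
        if np.any(np.diff(self.times_s) <= 0):
            raise DataError(f"fish {self.fish_id}: times must be strictly increasing")
        if self.positions_px.shape != (len(self.times_s), 2):
            raise DataError(
                f"fish {self.fish_id}: positions shape {self.positions_px.shape} "
                f"does not match {len(self.times_s)} frames"
            )
        if not 0.0 <= self.detection_fraction <= 1.0:
            raise DataError(f"fish {self.fish_id}: detection_fraction outside [0, 1]")

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of frames with a finite (kept) position."""
        return np.all(np.isfinite(self.positions_px), axis=1)

    @property
    def n_frames(self) -> int:
        return len(self.times_s)


@dataclass
class GroupRecording:
    """One tank's trajectories on a shared time grid, plus metadata."""

    site: str
    tank_id: str
    trajectories: list[Trajectory]
    calibration: CalibrationInfo
    sample_duration_s: float = 180.0

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise DataError(f"tank {self.tank_id}: no trajectories")
        t0 = self.trajectories[0].times_s
        for tr in self.trajectories[1:]:
            if len(tr.times_s) != len(t0) or not np.allclose(tr.times_s, t0):
                raise DataError(
                    f"tank {self.tank_id}: fish {tr.fish_id} is not on the common time grid"
                )
        if self.sample_duration_s <= 0:
            raise DataError(f"tank {self.tank_id}: non-positive sample duration")

    @property
    def n_fish(self) -> int:
        return len(self.trajectories)

    @property
    def times_s(self) -> np.ndarray:
        return self.trajectories[0].times_s

    @property
    def fish_ids(self) -> list[str]:
        return [tr.fish_id for tr in self.trajectories]

    def positions_array(self) -> np.ndarray:
        """Stacked positions with shape (n_fish, n_frames, 2), pixels."""
        return np.stack([tr.positions_px for tr in self.trajectories])


@dataclass
class LandmarkSet:
    """Seven digitized landmarks (mm) with specimen labels.

    Landmark order is fixed: (1) mouth, (2) posterior dorsal skull,
    (3) anterior dorsal fin, (4) caudal fin, (5) anterior anal fin,
    (6) ventral surface, (7) ventral anterior skull.
    """

    fish_id: str
    site: str
    sex: str
    landmarks_mm: np.ndarray

    def __post_init__(self) -> None:
        self.landmarks_mm = np.asarray(self.landmarks_mm, dtype=float)
        if self.landmarks_mm.shape != (N_LANDMARKS, 2):
            raise DataError(
                f"fish {self.fish_id}: expected {N_LANDMARKS} landmarks, "
                f"got shape {self.landmarks_mm.shape}"
            )
        if not np.all(np.isfinite(self.landmarks_mm)):
            raise DataError(f"fish {self.fish_id}: non-finite landmark coordinates")


_KEY_COLUMNS = ("site", "tank_id", "fish_id")


@dataclass
class EndpointTable:
    """Tidy endpoint values at fish or tank level, with per-column units.

    ``data`` is a DataFrame whose key columns are ``site``/``tank_id``
    (and ``fish_id`` at fish level); every other column is an endpoint
    and must have an entry in ``units`` (use "" for dimensionless).
    """

    data: pd.DataFrame
    units: dict[str, str]
    level: str = "fish"  # "fish" | "tank"

    def __post_init__(self) -> None:
        if self.level not in ("fish", "tank"):
            raise ConfigError(f"unknown table level {self.level!r}")
        keys = self.key_columns
        missing = [k for k in keys if k not in self.data.columns]
        if missing:
            raise DataError(f"endpoint table missing key columns {missing}")
        if len(self.data) and self.data.duplicated(subset=list(keys)).any():
            raise DataError("endpoint table has duplicate keys")
        for col in self.endpoint_columns:
            if col not in self.units:
                raise UnitError(f"no unit recorded for endpoint column {col!r}")

    @property
    def key_columns(self) -> tuple[str, ...]:
        return _KEY_COLUMNS if self.level == "fish" else _KEY_COLUMNS[:2]

    @property
    def endpoint_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in _KEY_COLUMNS]


# ---------------------------------------------------------------------------
# trajectory tables

_DIALECTS = {
    # column name in file -> canonical name
    "generic-csv": {
        "sep": ",",
        "columns": {"frame": "frame", "time_s": "time_s", "fish_id": "fish_id",
                    "x_px": "x_px", "y_px": "y_px"},
    },
    # ToxTrac real-space/tracking export: tab-separated Frame/Time/Arena/Track/X/Y
    "toxtrac": {
        "sep": "\t",
        "columns": {"Frame": "frame", "Time": "time_s", "Track": "fish_id",
                    "X": "x_px", "Y": "y_px"},
    },
}


def _interpolate_gaps(xy: np.ndarray, detected: np.ndarray, max_gap_frames: int) -> np.ndarray:
    """Fill runs of <= max_gap_frames missing frames by linear interpolation.

    Longer interior runs and any leading/trailing runs stay NaN.
    """
    out = xy.copy()
    n = len(detected)
    if not detected.any():
        return out
    miss = np.flatnonzero(~detected)
    if len(miss) == 0:
        return out
    # split miss into consecutive runs
    splits = np.flatnonzero(np.diff(miss) > 1) + 1
    for run in np.split(miss, splits):
        a, b = run[0] - 1, run[-1] + 1  # flanking detected frames
        if a < 0 or b >= n or not detected[a] or not detected[b]:
            continue  # leading/trailing gap: cannot interpolate
        if len(run) > max_gap_frames:
            continue
        frac = (run - a) / (b - a)
        out[run] = xy[a] + frac[:, None] * (xy[b] - xy[a])
    return out


def read_trajectory_table(
    path: str | Path,
    dialect: str,
    calibration: CalibrationInfo,
    *,
    site: str = "",
    tank_id: str | None = None,
    max_gap_frames: int = 5,
    sample_duration_s: float | None = None,
) -> GroupRecording:
    """Read a per-frame tracking export into a :class:`GroupRecording`.

    All fish are aligned to the union frame grid of the file.  Gaps of at
    most ``max_gap_frames`` frames are linearly interpolated; longer gaps
    are left NaN (excluded).  ``detection_fraction`` per fish counts
    detections before interpolation.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ConfigError(f"unknown trajectory dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    spec = _DIALECTS[dialect]
    sep = spec["sep"]
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(sep)]
    colmap = spec["columns"]
    try:
        pos = {canon: header.index(raw) for raw, canon in colmap.items()}
    except ValueError as exc:
        raise ParseError(f"{path}: line 1: missing required column ({exc})") from None

    records: dict[str, dict[int, tuple[float, float]]] = {}
    frame_time: dict[int, float] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(sep)
        try:
            frame = int(float(parts[pos["frame"]]))
            t = float(parts[pos["time_s"]])
            fid = parts[pos["fish_id"]].strip()
            x = float(parts[pos["x_px"]])
            y = float(parts[pos["y_px"]])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
        frame_time[frame] = t
        records.setdefault(fid, {})[frame] = (x, y)

    if not records:
        raise DataError(f"{path}: no data rows")
    frames = np.arange(min(frame_time), max(frame_time) + 1)
    n = len(frames)
    if n < 2:
        raise DataError(f"{path}: fewer than 2 frames")
    # time grid: use recorded times where present, fill by frame_rate otherwise
    t0_frame = frames[0]
    times = np.array(
        [frame_time.get(f, (f - t0_frame) / calibration.frame_rate + frame_time[min(frame_time)])
         for f in frames]
    )
    if np.any(np.diff(times) <= 0):
        raise DataError(f"{path}: frame grid times are not strictly increasing; cannot align")

    trajectories = []
    for fid in sorted(records):
        obs = records[fid]
        if len(obs) < 2:
            raise DataError(f"{path}: fish {fid} has fewer than 2 frames")
        xy = np.full((n, 2), np.nan)
        detected = np.zeros(n, dtype=bool)
        for f, (x, y) in obs.items():
            i = f - t0_frame
            xy[i] = (x, y)
            detected[i] = True
        frac = detected.mean()
        xy = _interpolate_gaps(xy, detected, max_gap_frames)
        trajectories.append(
            Trajectory(fish_id=fid, times_s=times, positions_px=xy, detection_fraction=float(frac))
        )
    duration = sample_duration_s if sample_duration_s is not None else float(n / calibration.frame_rate)
    return GroupRecording(
        site=site,
        tank_id=tank_id if tank_id is not None else path.stem,
        trajectories=trajectories,
        calibration=calibration,
        sample_duration_s=duration,
    )


def write_trajectory_table(group: GroupRecording, path: str | Path, dialect: str = "generic-csv") -> None:
    """Write a recording in one of the readable dialects (detected frames only)."""
    if dialect not in _DIALECTS:
        raise ConfigError(f"unknown trajectory dialect {dialect!r}")
    spec = _DIALECTS[dialect]
    sep = spec["sep"]
    inv = {canon: raw for raw, canon in spec["columns"].items()}
    order = ["frame", "time_s", "fish_id", "x_px", "y_px"]
    with open(path, "w") as fh:
        fh.write(sep.join(inv[c] for c in order) + "\n")
        for tr in group.trajectories:
            mask = tr.valid_mask
            for i in np.flatnonzero(mask):
                row = {
                    "frame": str(i),
                    "time_s": repr(float(tr.times_s[i])),
                    "fish_id": tr.fish_id,
                    "x_px": repr(float(tr.positions_px[i, 0])),
                    "y_px": repr(float(tr.positions_px[i, 1])),
                }
                fh.write(sep.join(row[c] for c in order) + "\n")


def qc_tracking_accuracy(group: GroupRecording, threshold: float = 0.80) -> dict:
    """Tracking-accuracy gate: the tank passes iff every fish's
    detection fraction is >= ``threshold`` (inclusive).

    Returns a JSON-serializable report naming failing fish.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigError(f"threshold must be in [0, 1], got {threshold}")
    fish = {
        tr.fish_id: {
            "detection_fraction": float(tr.detection_fraction),
            "pass": bool(tr.detection_fraction >= threshold),
        }
        for tr in group.trajectories
    }
    failing = sorted(fid for fid, r in fish.items() if not r["pass"])
    return {
        "site": group.site,
        "tank_id": group.tank_id,
        "threshold": float(threshold),
        "fish": fish,
        "failing_fish": failing,
        "tank_pass": not failing,
    }


# ---------------------------------------------------------------------------
# TPS landmark files

def read_tps(
    path: str | Path,
    metadata: pd.DataFrame | Mapping[str, Mapping[str, str]] | None = None,
    *,
    default_scale: float | None = None,
) -> list[LandmarkSet]:
    """Read a TPS landmark file (LM= blocks as written by tpsDIG).

    Coordinates are multiplied by the block's ``SCALE=`` factor to yield
    millimetres; without SCALE, ``default_scale`` is required.  Site/sex
    labels come from ``metadata``, a table keyed by image name or ID with
    columns ``site`` and ``sex`` (TPS itself carries no such fields).
    """
    path = Path(path)
    if isinstance(metadata, pd.DataFrame):
        meta: Mapping[str, Mapping[str, str]] = {
            str(k): row for k, row in metadata.set_index(metadata.columns[0]).iterrows()
        } if metadata.index.name is None and metadata.columns[0].lower() in ("id", "image", "fish_id") else {
            str(k): row for k, row in metadata.iterrows()
        }
    else:
        meta = metadata or {}

    sets: list[LandmarkSet] = []
    block_coords: list[tuple[float, float]] | None = None
    block_n = 0
    block_no = 0
    attrs: dict[str, str] = {}

    def finish_block(lineno: int) -> None:
        nonlocal block_coords, attrs
        if block_coords is None:
            return
        if len(block_coords) != block_n:
            raise ParseError(
                f"{path}: block {block_no} (ending line {lineno}): "
                f"expected {block_n} coordinate lines, got {len(block_coords)}"
            )
        if block_n != N_LANDMARKS:
            raise ParseError(
                f"{path}: block {block_no}: LM={block_n}, expected LM={N_LANDMARKS}"
            )
        scale = attrs.get("SCALE")
        if scale is not None:
            factor = float(scale)
        elif default_scale is not None:
            factor = default_scale
        else:
            raise UnitError(
                f"{path}: block {block_no}: no SCALE= line and no default_scale given; "
                "units would be ambiguous"
            )
        coords = np.asarray(block_coords, dtype=float) * factor
        key = attrs.get("IMAGE") or attrs.get("ID") or f"specimen_{block_no}"
        row = meta.get(key, meta.get(Path(key).stem, {}))
        sets.append(
            LandmarkSet(
                fish_id=str(key),
                site=str(row.get("site", "")),
                sex=str(row.get("sex", "unknown")),
                landmarks_mm=coords,
            )
        )
        block_coords = None
        attrs = {}

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.upper().startswith("LM="):
                finish_block(lineno)
                block_no += 1
                try:
                    block_n = int(line.split("=", 1)[1])
                except ValueError:
                    raise ParseError(f"{path}: line {lineno}: bad LM= count") from None
                block_coords = []
            elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
                key, _, val = line.partition("=")
                attrs[key.strip().upper()] = val.strip()
            else:
                if block_coords is None:
                    raise ParseError(f"{path}: line {lineno}: coordinates before any LM= header")
                parts = line.split()
                try:
                    x, y = float(parts[0]), float(parts[1])
                except (ValueError, IndexError):
                    raise ParseError(f"{path}: line {lineno}: bad coordinate line {line!r}") from None
                block_coords.append((x, y))
    finish_block(lineno if block_coords is not None else 0)
    return sets


def write_tps(sets: Sequence[LandmarkSet], path: str | Path, scale: float = 1.0) -> None:
    """Write landmark sets as TPS blocks (coordinates in mm / scale)."""
    with open(path, "w") as fh:
        for i, lm in enumerate(sets):
            fh.write(f"LM={N_LANDMARKS}\n")
            for x, y in lm.landmarks_mm / scale:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write(f"IMAGE={lm.fish_id}\n")
            fh.write(f"ID={i}\n")
            fh.write(f"SCALE={scale!r}\n")


# ---------------------------------------------------------------------------
# endpoint tables

def write_endpoint_table(table: EndpointTable, path: str | Path) -> None:
    """Write a tidy delimited endpoint table with unit-annotated headers.

    Endpoint columns are written as ``name [unit]``; floats use repr so
    the companion reader round-trips losslessly.
    """
    if len(table.data) == 0:
        logger.warning("writing empty endpoint table to %s", path)
    cols = list(table.key_columns) + table.endpoint_columns
    header = []
    for c in cols:
        header.append(f"{c} [{table.units[c]}]" if c in table.units else c)
    with open(path, "w") as fh:
        fh.write("# level=%s\n" % table.level)
        fh.write("\t".join(header) + "\n")
        for _, row in table.data[cols].iterrows():
            out = []
            for c in cols:
                v = row[c]
                out.append(repr(float(v)) if isinstance(v, (float, np.floating)) else str(v))
            fh.write("\t".join(out) + "\n")


def read_endpoint_table(path: str | Path) -> EndpointTable:
    """Read a table written by :func:`write_endpoint_table`."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# level="):
            raise ParseError(f"{path}: line 1: missing level header")
        level = first.split("=", 1)[1]
        header = fh.readline().rstrip("\n").split("\t")
        units: dict[str, str] = {}
        cols: list[str] = []
        for h in header:
            if h.endswith("]") and " [" in h:
                name, _, unit = h.rpartition(" [")
                units[name] = unit[:-1]
                cols.append(name)
            else:
                cols.append(h)
        rows = []
        for lineno, line in enumerate(fh, start=3):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise ParseError(f"{path}: line {lineno}: expected {len(cols)} fields")
            rows.append(parts)
    data = pd.DataFrame(rows, columns=cols)
    for c in cols:
        if c in units:
            data[c] = data[c].astype(float)
    return EndpointTable(data=data, units=units, level=level)
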