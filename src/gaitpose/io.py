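"""Keypoint and result I/O.

Keypoint time series travel as CSV: one row per frame (wide format, columns
``<landmark>_x``/``<landmark>_y``/optional ``<landmark>_v``) or long format
(``frame,landmark,x,y[,v]``), auto-detected from the header. The capture rate
is given either as an argument or as a ``# fps=<value>`` comment line at the
top of the file. Session results are serialized as a JSON document with
declared units.

Coordinates use the image convention: origin top-left, y increases downward,
units are pixels. Only the ten gait-relevant landmarks (hip, knee, ankle,
heel, toe on each side) are required; extra columns from a full-body pose
model are ignored.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, SchemaError

SIDES = ("left", "right")
ROLES = ("hip", "knee", "ankle", "heel", "toe")


def landmark(side: str, role: str) -> str:
    """Canonical landmark id for a (side, role) pair, e.g. ('left','heel') -> 'left_heel'."""
    if side not in SIDES:
        raise KeyError(f"unknown side {side!r}; expected one of {SIDES}")
    if role not in ROLES:
        raise KeyError(f"unknown role {role!r}; expected one of {ROLES}")
    return f"{side}_{role}"


#: The ten landmarks every keypoint table must provide.
LANDMARKS = tuple(landmark(s, r) for s in SIDES for r in ROLES)


@dataclass(frozen=True)
class LandmarkSchema:
    """Ordered landmark identifiers with (side, role) lookup."""

    names: tuple = LANDMARKS

    def lookup(self, side: str, role: str) -> str:
        name = landmark(side, role)
        if name not in self.names:
            raise KeyError(name)
        return name


DEFAULT_SCHEMA = LandmarkSchema()


@dataclass
class KeypointSeries:
    """Frame-indexed 2D pixel trajectories for the gait landmark set.

    Attributes
    ----------
    fps : float
        Capture rate in frames per second (> 0).
    coords : dict[str, np.ndarray]
        Per-landmark ``(n_frames, 2)`` float arrays of (x, y) pixel
        coordinates.
    visibility : dict[str, np.ndarray] | None
        Optional per-landmark per-frame visibility scores in [0, 1].
    failed_sides : dict[str, str]
        Sides whose data could not be repaired at load time (gap too long),
        mapped to a human-readable reason. Analysis skips these sides.
    """

    fps: float
    coords: dict
    visibility: Optional[dict] = None
    failed_sides: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.fps > 0:
            raise ConfigurationError(f"fps must be > 0, got {self.fps}")
        lengths = {len(v) for v in self.coords.values()}
        if len(lengths) > 1:
            raise FormatError(f"landmark streams have unequal lengths: {sorted(lengths)}")
        for name, arr in self.coords.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise FormatError(f"landmark {name!r} must be (n, 2), got {arr.shape}")
            self.coords[name] = arr

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.coords.values()))) if self.coords else 0

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def xy(self, name: str) -> np.ndarray:
        return self.coords[name]

    def slice(self, start: int, stop: Optional[int] = None) -> "KeypointSeries":
        """Frame-window view (copied) of the series; fps unchanged."""
        coords = {k: v[start:stop].copy() for k, v in self.coords.items()}
        vis = None
        if self.visibility is not None:
            vis = {k: v[start:stop].copy() for k, v in self.visibility.items()}
        return KeypointSeries(self.fps, coords, vis, dict(self.failed_sides))


# ---------------------------------------------------------------------------
# keypoint CSV
# ---------------------------------------------------------------------------

def _read_fps_comment(path: Path) -> Optional[float]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("fps"):
                    try:
                        return float(body.split("=", 1)[1])
                    except (IndexError, ValueError) as exc:
                        raise ConfigurationError(f"unparseable fps comment: {line!r}") from exc
            else:
                break
    return None


def _interpolate_missing(x: np.ndarray, max_gap: int) -> tuple[np.ndarray, Optional[int]]:
    """Linearly fill NaN runs of length <= max_gap; return longest bad gap if any."""
    isnan = np.isnan(x)
    if not isnan.any():
        return x, None
    # locate NaN runs
    idx = np.flatnonzero(isnan)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    longest_bad = None
    good = np.flatnonzero(~isnan)
    if good.size == 0:
        return x, len(x)
    filled = x.copy()
    filled[isnan] = np.interp(np.flatnonzero(isnan), good, x[good])
    for run in runs:
        gap = len(run)
        # boundary runs count as gaps too (extrapolation is a repair we refuse
        # beyond max_gap just like interior gaps)
        if gap > max_gap:
            longest_bad = gap if longest_bad is None else max(longest_bad, gap)
    return filled, longest_bad


def read_keypoints(
    path,
    fps: Optional[float] = None,
    *,
    schema: LandmarkSchema = DEFAULT_SCHEMA,
    visibility_threshold: float = 0.1,
    max_gap_frames: int = 5,
) -> KeypointSeries:
    """Read a keypoint CSV (wide or long format, auto-detected).

    ``fps`` may be supplied as an argument or as a ``# fps=<value>`` comment
    line in the file; the argument wins. Samples with visibility below
    ``visibility_threshold`` are treated as missing and linearly interpolated
    up to ``max_gap_frames``-frame gaps; a longer gap marks that body side as
    failed (analysis of the other side proceeds).
    """
    path = Path(path)
    file_fps = _read_fps_comment(path)
    fps = fps if fps is not None else file_fps
    if fps is None:
        raise ConfigurationError(
            f"fps not given and no '# fps=' comment found in {path}"
        )

    df = pd.read_csv(path, comment="#")
    cols = set(df.columns)
    if {"landmark", "x", "y"} <= cols:
        df = _long_to_wide(df)
        cols = set(df.columns)

    if "frame" not in cols:
        raise FormatError(f"{path}: missing required 'frame' column")
    frames = df["frame"].to_numpy()
    if len(frames) and not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
        raise FormatError(f"{path}: frame index must be consecutive and monotone")

    coords: dict = {}
    visibility: dict = {}
    has_vis = False
    for name in schema.names:
        for axis in ("x", "y"):
            col = f"{name}_{axis}"
            if col not in cols:
                raise SchemaError(f"{path}: missing required landmark column {col!r}")
        xy = df[[f"{name}_x", f"{name}_y"]].to_numpy(dtype=float)
        vcol = f"{name}_v"
        if vcol in cols:
            has_vis = True
            v = df[vcol].to_numpy(dtype=float)
        else:
            v = np.ones(len(df))
        visibility[name] = v
        xy = xy.copy()
        xy[v < visibility_threshold] = np.nan
        coords[name] = xy

    failed_sides: dict = {}
    for name in schema.names:
        xy = coords[name]
        side = name.split("_", 1)[0]
        for axis in range(2):
            filled, bad = _interpolate_missing(xy[:, axis], max_gap_frames)
            xy[:, axis] = filled
            if bad is not None and side not in failed_sides:
                failed_sides[side] = (
                    f"landmark {name} has a {bad}-frame low-visibility gap "
                    f"(max repairable: {max_gap_frames})"
                )
    return KeypointSeries(
        fps=float(fps),
        coords=coords,
        visibility=visibility if has_vis else None,
        failed_sides=failed_sides,
    )


def _long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    value_cols = ["x", "y"] + (["v"] if "v" in df.columns else [])
    wide = df.pivot(index="frame", columns="landmark", values=value_cols)
    wide.columns = [f"{lm}_{val}" for val, lm in wide.columns]
    return wide.reset_index()


def write_keypoints(series: KeypointSeries, path) -> None:
    """Write a KeypointSeries as wide-format CSV with an fps comment line."""
    path = Path(path)
    data = {"frame": np.arange(series.n_frames)}
    for name in series.coords:
        xy = series.coords[name]
        data[f"{name}_x"] = xy[:, 0]
        data[f"{name}_y"] = xy[:, 1]
        if series.visibility is not None and name in series.visibility:
            data[f"{name}_v"] = series.visibility[name]
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        fh.write(f"# fps={series.fps:g}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# session results (JSON)
# ---------------------------------------------------------------------------

RESULT_UNITS = {
    "times": "s",
    "angles": "deg",
    "cadence": "steps/min",
}


@dataclass
class SideResult:
    """Per-side outcome bundle; ``error`` is set when the side failed."""

    strides: list = field(default_factory=list)
    n_ic: int = 0
    n_fc: int = 0
    foot_strike: Optional[str] = None  # class name or "uncalibrated"
    mean_foot_deviation_deg: Optional[float] = None
    per_strike_classes: list = field(default_factory=list)
    baseline_foot_angle_deg: Optional[float] = None
    knee_flexion_mean_waveform: Optional[list] = None
    n_degenerate_frames: int = 0
    warnings: list = field(default_factory=list)
    error: Optional[str] = None


@dataclass
class SessionResult:
    """Session-level gait outcomes plus a configuration echo."""

    fps: float
    duration_s: float
    cadence_spm: float
    sides: dict = field(default_factory=dict)  # side -> SideResult
    config: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    units: dict = field(default_factory=lambda: dict(RESULT_UNITS))

    def side(self, name: str) -> SideResult:
        return self.sides[name]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_result(result: SessionResult, path) -> None:
    """Serialize a SessionResult to JSON with stable key order and units."""
    doc = _to_jsonable(result)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_result(path) -> SessionResult:
    """Read a SessionResult JSON written by :func:`write_result`."""
    from .outcomes import StrideMetrics  # local import avoids a cycle

    with open(path) as fh:
        doc = json.load(fh)
    sides = {}
    for side_name, sdoc in doc.get("sides", {}).items():
        strides = [StrideMetrics(**s) for s in sdoc.pop("strides", [])]
        sides[side_name] = SideResult(strides=strides, **sdoc)
    return SessionResult(
        fps=doc["fps"],
        duration_s=doc["duration_s"],
        cadence_spm=doc["cadence_spm"],
        sides=sides,
        config=doc.get("config", {}),
        warnings=doc.get("warnings", []),
        units=doc.get("units", dict(RESULT_UNITS)),
    )
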