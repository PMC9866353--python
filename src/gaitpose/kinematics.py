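"""Joint angles from keypoint triplets.

All angles are the unsigned angle at a vertex between two rays, computed via
the vector scalar product:

    theta = arccos( (a-v).(b-v) / (|a-v| |b-v|) )   in degrees, in [0, 180].

Two per-frame angle signals drive the pipeline:

* the **leg extension angle** at the knee between knee->hip and knee->ankle
  (180 deg = fully extended; its minimum marks maximum knee flexion), and
* the **foot pitch angle** at the heel between heel->toe and a reference
  point vH placed directly above the heel (the angle is invariant to the
  length of that vertical offset, so a unit offset is used).

Side-specific direction (dorsi- vs plantar-flexion) is not encoded in the
angle sign; it is recovered downstream as deviation from a calibrated
standing baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .io import KeypointSeries, landmark

_EPS = 1e-9


@dataclass
class AngleSeries:
    """A per-frame angle signal in degrees for one side and one angle kind."""

    kind: str  # 'leg_extension' | 'foot_pitch'
    side: str  # 'left' | 'right'
    values: np.ndarray  # degrees, each in [0, 180]
    fps: float
    n_degenerate: int = 0  # frames whose value was carried over

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self):
        return len(self.values)


def joint_angle(a, vertex, b) -> float:
    """Unsigned angle (degrees) at ``vertex`` between rays to ``a`` and ``b``."""
    a = np.asarray(a, dtype=float)
    v = np.asarray(vertex, dtype=float)
    b = np.asarray(b, dtype=float)
    u, w = a - v, b - v
    nu, nw = np.hypot(*u), np.hypot(*w)
    if nu <= _EPS:
        raise DegenerateGeometryError("point 'a' coincides with the vertex")
    if nw <= _EPS:
        raise DegenerateGeometryError("point 'b' coincides with the vertex")
    cos = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def _angles_vectorized(a: np.ndarray, v: np.ndarray, b: np.ndarray):
    """Per-frame angles with degenerate frames carried over from the last good frame.

    Returns (values, n_degenerate). Raises if the first frame is degenerate.
    """
    u, w = a - v, b - v
    nu = np.linalg.norm(u, axis=1)
    nw = np.linalg.norm(w, axis=1)
    bad = (nu <= _EPS) | (nw <= _EPS)
    denom = np.where(bad, 1.0, nu * nw)
    cos = np.clip(np.einsum("ij,ij->i", u, w) / denom, -1.0, 1.0)
    vals = np.degrees(np.arccos(cos))
    n_bad = int(bad.sum())
    if n_bad:
        if bad[0]:
            raise DegenerateGeometryError(
                "first frame has coincident keypoints; cannot carry over a value"
            )
        # forward-fill degenerate frames with the previous valid value
        idx = np.arange(len(vals))
        idx[bad] = 0
        idx = np.maximum.accumulate(idx)
        vals = vals[idx]
    return vals, n_bad


def leg_extension_series(series: KeypointSeries, side: str) -> AngleSeries:
    """Per-frame hip-knee-ankle angle (degrees) for one side."""
    hip = series.xy(landmark(side, "hip"))
    knee = series.xy(landmark(side, "knee"))
    ankle = series.xy(landmark(side, "ankle"))
    vals, n_bad = _angles_vectorized(hip, knee, ankle)
    return AngleSeries("leg_extension", side, vals, series.fps, n_bad)


def foot_pitch_series(series: KeypointSeries, side: str) -> AngleSeries:
    """Per-frame toe-heel-vH angle (degrees), vH one pixel directly above the heel."""
    heel = series.xy(landmark(side, "heel"))
    toe = series.xy(landmark(side, "toe"))
    v_h = heel + np.array([0.0, -1.0])  # image coords: up is -y
    vals, n_bad = _angles_vectorized(toe, heel, v_h)
    return AngleSeries("foot_pitch", side, vals, series.fps, n_bad)
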