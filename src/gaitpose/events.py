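"""Gait-event detection from the leg-extension angle signal.

During running the leg approaches full extension (hip-knee-ankle angle
tending towards 180 deg) twice per stride: once at initial contact (IC, foot
strikes the ground) and once at final contact (FC, toe-off). Detection runs
in three steps:

1. a dynamic threshold — by default the 90th percentile of the smoothed
   leg-extension angle (a 90%-of-maximum variant is available);
2. zero-crossing gradient maxima peak detection above the threshold;
3. IC/FC labelling from the minimum of the signal in a lookback window
   before each peak: the signal dips far lower before an IC (deep knee
   flexion in swing) than before an FC (shallow mid-stance dip). Labels are
   assigned pair-relatively (the deeper preceding minimum of a consecutive
   peak pair marks the IC) and then propagated to enforce strict IC/FC
   alternation; peaks that break alternation are dropped with a warning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .errors import (
    ConfigurationError,
    DegenerateSignalError,
    InsufficientEventsError,
)
from .io import KeypointSeries
from .kinematics import AngleSeries, leg_extension_series
from .preprocess import SmoothingConfig, smooth_series

IC = "IC"
FC = "FC"


@dataclass(frozen=True)
class GaitEvent:
    """A labelled gait event at a frame index on one side."""

    label: str  # 'IC' | 'FC'
    frame: int
    side: str
    angle_at_event: float  # degrees
    preceding_min: float  # degrees, minimum in the lookback window

    @property
    def is_ic(self) -> bool:
        return self.label == IC


@dataclass(frozen=True)
class DetectionConfig:
    """Event-detection parameters.

    threshold_mode : 'percentile_90' (90th percentile of the angle signal,
        default) or 'fraction_of_max' (90% of the maximum observed angle).
    min_peak_separation_s : peaks closer than this are merged, keeping the
        higher one (default 0.05 s).
    lookback_s : window before each peak searched for the preceding minimum
        (default 0.30 s — long enough to reach into the swing phase, clipped
        at the previous peak).
    min_events : minimum number of labelled events for a usable bout.
    ic_min_gap_deg : optional fixed-depth rule — if set, a peak is IC when
        its peak-to-preceding-minimum drop is at least this many degrees;
        by default the scale-free relative rule is used instead.
    """

    threshold_mode: str = "percentile_90"
    min_peak_separation_s: float = 0.05
    lookback_s: float = 0.30
    min_events: int = 4
    ic_min_gap_deg: Optional[float] = None

    def __post_init__(self):
        if self.threshold_mode not in ("percentile_90", "fraction_of_max"):
            raise ConfigurationError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.min_peak_separation_s <= 0 or self.lookback_s <= 0 or self.min_events <= 0:
            raise ConfigurationError("detection parameters must be positive")


def dynamic_threshold(angles: AngleSeries, config: DetectionConfig = DetectionConfig()) -> float:
    """Detection threshold in degrees for a given angle series."""
    x = angles.values
    if np.ptp(x) <= 1e-12:
        raise DegenerateSignalError("no gait dynamics detected (constant angle signal)")
    if config.threshold_mode == "fraction_of_max":
        return 0.9 * float(np.max(x))
    return float(np.percentile(x, 90))


def find_peaks(
    angles: AngleSeries, threshold: float, config: DetectionConfig = DetectionConfig()
) -> List[int]:
    """Frames of gradient zero-crossings (+ to -) strictly above the threshold.

    Plateaus resolve to the plateau midpoint (earlier frame on ties);
    peaks closer than ``min_peak_separation_s`` merge, keeping the higher.
    """
    x = angles.values
    if len(x) < 3:
        return []
    peaks, _ = _scipy_find_peaks(x, plateau_size=1)
    peaks = [int(p) for p in peaks if x[p] > threshold]
    min_sep = max(1, int(round(config.min_peak_separation_s * angles.fps)))
    merged: List[int] = []
    for p in peaks:
        if merged and p - merged[-1] < min_sep:
            if x[p] > x[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)
    return merged


def _preceding_minima(x: np.ndarray, peaks: Sequence[int], lookback: int) -> np.ndarray:
    """Minimum of x in the lookback window before each peak, clipped at the previous peak."""
    mins = np.empty(len(peaks))
    for j, p in enumerate(peaks):
        start = p - lookback
        if j > 0:
            start = max(start, peaks[j - 1] + 1)
        start = max(start, 0)
        mins[j] = x[start:p].min() if p > start else x[p]
    return mins


def _depth_boundary(mins: np.ndarray) -> float:
    """Scale-free boundary between deep (pre-IC) and shallow (pre-FC) minima.

    Two-means clustering on the 1-D preceding-minimum depths, initialized at
    the extremes; with two peaks this reduces to the pairwise relative rule
    (the deeper minimum of the pair marks the IC).
    """
    c_deep, c_shallow = float(mins.min()), float(mins.max())
    for _ in range(50):
        b = (c_deep + c_shallow) / 2
        deep, shallow = mins[mins <= b], mins[mins > b]
        if len(deep) == 0 or len(shallow) == 0:
            break
        nd, ns = float(deep.mean()), float(shallow.mean())
        if nd == c_deep and ns == c_shallow:
            break
        c_deep, c_shallow = nd, ns
    return (c_deep + c_shallow) / 2


def label_events(
    angles: AngleSeries, peaks: Sequence[int], config: DetectionConfig = DetectionConfig()
) -> tuple:
    """Label peaks as IC/FC events.

    Returns ``(events, n_warnings)`` where ``n_warnings`` counts peaks
    dropped to repair broken alternation. The first peak of the bout is
    discarded when its lookback window is truncated by the signal start.
    """
    x = angles.values
    lookback = max(1, int(round(config.lookback_s * angles.fps)))
    peaks = [int(p) for p in peaks]
    if peaks and peaks[0] - lookback < 0:
        peaks = peaks[1:]
    if len(peaks) < 2:
        raise InsufficientEventsError(
            f"need at least 2 peaks with full lookback windows, got {len(peaks)}"
        )

    n_warnings = 0
    if config.ic_min_gap_deg is not None:
        # fixed-depth variant: IC iff the peak rises >= gap above its preceding min
        while True:
            mins = _preceding_minima(x, peaks, lookback)
            labels = [
                IC if x[p] - m >= config.ic_min_gap_deg else FC
                for p, m in zip(peaks, mins)
            ]
            dup = next(
                (j for j in range(len(labels) - 1) if labels[j] == labels[j + 1]), None
            )
            if dup is None:
                break
            # keep the more extreme of the clashing pair
            if labels[dup] == IC:
                drop = dup if mins[dup] > mins[dup + 1] else dup + 1
            else:
                drop = dup if mins[dup] < mins[dup + 1] else dup + 1
            del peaks[drop]
            n_warnings += 1
            if len(peaks) < 2:
                raise InsufficientEventsError("alternation repair exhausted the peak list")
    else:
        # relative depth rule: deep preceding minimum = IC, shallow = FC;
        # alternation conflicts (spurious or missed peaks) are repaired by
        # dropping the peak whose depth is least decisive
        while True:
            mins = _preceding_minima(x, peaks, lookback)
            boundary = _depth_boundary(mins)
            labels = [IC if m <= boundary else FC for m in mins]
            dup = next(
                (j for j in range(len(labels) - 1) if labels[j] == labels[j + 1]), None
            )
            if dup is None:
                break
            confidence = np.abs(mins[[dup, dup + 1]] - boundary)
            drop = dup if confidence[0] <= confidence[1] else dup + 1
            del peaks[drop]
            n_warnings += 1
            if len(peaks) < 2:
                raise InsufficientEventsError("alternation repair exhausted the peak list")

    events = [
        GaitEvent(label, p, angles.side, float(x[p]), float(m))
        for label, p, m in zip(labels, peaks, mins)
    ]
    return events, n_warnings


def detect_events(
    series: KeypointSeries,
    side: str,
    smoothing: SmoothingConfig = SmoothingConfig(),
    config: DetectionConfig = DetectionConfig(),
    *,
    presmoothed: bool = False,
) -> List[GaitEvent]:
    """Full per-side event detection: smooth, angle, threshold, peaks, label."""
    smoothed = series if presmoothed else smooth_series(series, smoothing)
    angles = leg_extension_series(smoothed, side)
    threshold = dynamic_threshold(angles, config)
    peaks = find_peaks(angles, threshold, config)
    events, _ = label_events(angles, peaks, config)
    if len(events) < config.min_events:
        raise InsufficientEventsError(
            f"detected {len(events)} events; need at least {config.min_events}"
        )
    return events
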