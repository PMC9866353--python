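"""Gait outcomes from labelled events and angle series.

Temporal outcomes per stride x (frames divided by the capture rate):

    contact time   CT  = (FC_x     - IC_x) / fps
    swing time     ST  = (IC_{x+1} - FC_x) / fps
    step time      StT = (IC_{x+1} - IC_x) / fps        (StT = CT + ST)

Cadence is the average number of steps per second times 60, counting initial
contacts on both feet. Knee flexion is reported at IC, at FC, and as the
minimum leg-extension angle between consecutive same-side ICs (i.e. maximum
flexion), plus a stride-time-normalized mean waveform. Foot-strike class
comes from the foot-pitch angle at IC relative to a standing-calibration
baseline: a mean deviation above +5 deg is a forefoot strike, below -5 deg a
rearfoot strike, and anything between (inclusive) a midfoot strike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .errors import (
    CalibrationError,
    ContractError,
    GaitposeError,
    SessionError,
)
from .events import FC, IC, DetectionConfig, GaitEvent, detect_events
from .io import SIDES, KeypointSeries, SessionResult, SideResult
from .kinematics import AngleSeries, foot_pitch_series, leg_extension_series
from .preprocess import SmoothingConfig, smooth_series

logger = logging.getLogger(__name__)

FOREFOOT = "forefoot"
MIDFOOT = "midfoot"
REARFOOT = "rearfoot"
FOOT_STRIKE_CLASSES = (FOREFOOT, MIDFOOT, REARFOOT)

#: samples in the stride-normalized (0-100%) waveform
WAVEFORM_SAMPLES = 101


@dataclass
class StrideMetrics:
    """Per-stride outcomes. Times in seconds, angles in degrees.

    ``swing_time``/``step_time`` are None for the final stride of a bout
    (no successor IC). Frames are kept for traceability and alignment.
    """

    stride_index: int
    side: str
    ic_frame: int
    fc_frame: int
    next_ic_frame: Optional[int] = None
    contact_time: Optional[float] = None
    swing_time: Optional[float] = None
    step_time: Optional[float] = None
    knee_flexion_at_ic: Optional[float] = None
    knee_flexion_at_fc: Optional[float] = None
    knee_flexion_min: Optional[float] = None
    foot_angle_at_ic: Optional[float] = None
    foot_deviation_at_ic: Optional[float] = None


@dataclass(frozen=True)
class CalibrationBaseline:
    """Standing foot-pitch baseline used to zero the strike-angle deviation."""

    side: str
    baseline_foot_angle: float  # degrees
    n_frames_used: int


@dataclass(frozen=True)
class FootStrikeConfig:
    threshold_deg: float = 5.0
    min_calibration_s: float = 0.5
    max_calibration_sd_deg: float = 2.0
    velocity_check: bool = False  # diagnostic toe-vs-heel velocity cross-check


@dataclass(frozen=True)
class AnalysisConfig:
    """Bundle of all pipeline parameters."""

    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    footstrike: FootStrikeConfig = field(default_factory=FootStrikeConfig)

    def echo(self) -> dict:
        return {
            "smoothing": {"window": self.smoothing.window, "edge_mode": self.smoothing.edge_mode,
                          "centered": self.smoothing.centered},
            "events": {
                "threshold_mode": self.detection.threshold_mode,
                "min_peak_separation_s": self.detection.min_peak_separation_s,
                "lookback_s": self.detection.lookback_s,
                "min_events": self.detection.min_events,
            },
            "footstrike": {
                "threshold_deg": self.footstrike.threshold_deg,
                "min_calibration_s": self.footstrike.min_calibration_s,
                "velocity_check": self.footstrike.velocity_check,
            },
        }


# ---------------------------------------------------------------------------
# temporal outcomes
# ---------------------------------------------------------------------------

def _check_alternation(events: Sequence[GaitEvent]):
    if not events:
        raise ContractError("empty event list")
    for a, b in zip(events, events[1:]):
        if b.frame <= a.frame:
            raise ContractError("events must strictly increase in frame")
        if a.label == b.label:
            raise ContractError(f"events must alternate IC/FC; got {a.label},{b.label}")


def temporal_outcomes(events: Sequence[GaitEvent], fps: float) -> List[StrideMetrics]:
    """Contact/swing/step time per stride from an alternating event list.

    Leading FC events (a bout that starts mid-stance) are ignored; the final
    IC-FC pair without a successor IC yields contact time only.
    """
    if fps <= 0:
        raise ContractError(f"fps must be > 0, got {fps}")
    _check_alternation(events)
    evs = list(events)
    if evs and evs[0].label == FC:
        evs = evs[1:]
    strides: List[StrideMetrics] = []
    # evs is IC, FC, IC, FC, ...
    for x in range(0, len(evs) - 1, 2):
        ic, fc = evs[x], evs[x + 1]
        next_ic = evs[x + 2] if x + 2 < len(evs) else None
        sm = StrideMetrics(
            stride_index=x // 2,
            side=ic.side,
            ic_frame=ic.frame,
            fc_frame=fc.frame,
            next_ic_frame=None if next_ic is None else next_ic.frame,
            contact_time=(fc.frame - ic.frame) / fps,
        )
        if next_ic is not None:
            sm.swing_time = (next_ic.frame - fc.frame) / fps
            sm.step_time = (next_ic.frame - ic.frame) / fps
        strides.append(sm)
    return strides


def cadence(
    events_left: Sequence[GaitEvent],
    events_right: Sequence[GaitEvent],
    duration_s: float,
) -> float:
    """Steps per minute: total IC count across both sides over the analyzed window."""
    if duration_s <= 0:
        raise ContractError(f"duration_s must be > 0, got {duration_s}")
    n_ic = sum(e.is_ic for e in events_left) + sum(e.is_ic for e in events_right)
    if n_ic == 0:
        logger.warning("no initial contacts found; cadence reported as 0")
        return 0.0
    return n_ic / duration_s * 60.0


# ---------------------------------------------------------------------------
# knee flexion
# ---------------------------------------------------------------------------

@dataclass
class KneeFlexionSummary:
    per_stride: List[dict]  # at_ic, at_fc, minimum (degrees) per complete stride
    mean_waveform: np.ndarray  # 101 samples, 0-100% of the stride


def knee_flexion_summary(
    angles: AngleSeries, events: Sequence[GaitEvent]
) -> KneeFlexionSummary:
    """Knee angles at IC, at FC, and the minimum within each IC-to-IC stride,
    plus the stride-normalized mean leg-extension waveform (101 samples)."""
    _check_alternation(events)
    x = angles.values
    evs = list(events)
    if evs and evs[0].label == FC:
        evs = evs[1:]
    per_stride: List[dict] = []
    waveforms = []
    grid = np.linspace(0.0, 1.0, WAVEFORM_SAMPLES)
    for j in range(0, len(evs) - 2, 2):
        ic, fc, next_ic = evs[j], evs[j + 1], evs[j + 2]
        seg = x[ic.frame: next_ic.frame + 1]
        per_stride.append(
            {
                "at_ic": float(x[ic.frame]),
                "at_fc": float(x[fc.frame]),
                "minimum": float(seg.min()),
            }
        )
        t = np.linspace(0.0, 1.0, len(seg))
        waveforms.append(np.interp(grid, t, seg))
    if waveforms:
        mean_wave = np.mean(waveforms, axis=0)
    else:
        mean_wave = np.full(WAVEFORM_SAMPLES, np.nan)
    return KneeFlexionSummary(per_stride, mean_wave)


# ---------------------------------------------------------------------------
# foot strike
# ---------------------------------------------------------------------------

def calibrate_baseline(
    static: KeypointSeries,
    side: str,
    config: FootStrikeConfig = FootStrikeConfig(),
    smoothing: SmoothingConfig = SmoothingConfig(),
) -> CalibrationBaseline:
    """Standing foot-pitch baseline from a static segment.

    The segment must span at least ``min_calibration_s`` and hold still
    (per-frame foot-pitch SD below ``max_calibration_sd_deg``).
    """
    if static.duration_s < config.min_calibration_s:
        raise ContractError(
            f"static segment of {static.duration_s:.3f} s is shorter than the "
            f"required {config.min_calibration_s} s"
        )
    pitch = foot_pitch_series(smooth_series(static, smoothing), side)
    sd = float(np.std(pitch.values))
    if sd >= config.max_calibration_sd_deg:
        raise CalibrationError(
            f"{side} foot pitch SD {sd:.2f} deg during calibration exceeds "
            f"{config.max_calibration_sd_deg} deg; segment is not static"
        )
    return CalibrationBaseline(side, float(np.mean(pitch.values)), len(pitch))


def classify_foot_strike(
    deviations_at_ic: Sequence[float], threshold_deg: float = 5.0
) -> tuple:
    """Session-level foot-strike class from per-IC baseline deviations.

    The mean deviation is computed first and then classified (strictly above
    +threshold: forefoot; strictly below -threshold: rearfoot; the closed
    interval between: midfoot). Returns ``(class, mean_deviation)``.
    """
    if len(deviations_at_ic) == 0:
        raise ContractError("need at least one IC deviation to classify foot strike")
    mean_dev = float(np.mean(deviations_at_ic))
    if mean_dev > threshold_deg:
        cls = FOREFOOT
    elif mean_dev < -threshold_deg:
        cls = REARFOOT
    else:
        cls = MIDFOOT
    return cls, mean_dev


def _classify_one(dev: float, threshold_deg: float) -> str:
    cls, _ = classify_foot_strike([dev], threshold_deg)
    return cls


# ---------------------------------------------------------------------------
# session pipeline
# ---------------------------------------------------------------------------

def _analyze_side(
    smoothed: KeypointSeries,
    side: str,
    baseline: Optional[CalibrationBaseline],
    config: AnalysisConfig,
) -> SideResult:
    events = detect_events(
        smoothed, side, config.smoothing, config.detection, presmoothed=True
    )
    strides = temporal_outcomes(events, smoothed.fps)
    leg = leg_extension_series(smoothed, side)
    knee = knee_flexion_summary(leg, events)
    pitch = foot_pitch_series(smoothed, side)

    for sm, kf in zip(strides, knee.per_stride):
        sm.knee_flexion_at_ic = kf["at_ic"]
        sm.knee_flexion_at_fc = kf["at_fc"]
        sm.knee_flexion_min = kf["minimum"]
    for sm in strides:
        sm.foot_angle_at_ic = float(pitch.values[sm.ic_frame])
        if baseline is not None:
            sm.foot_deviation_at_ic = sm.foot_angle_at_ic - baseline.baseline_foot_angle

    result = SideResult(
        strides=strides,
        n_ic=sum(e.is_ic for e in events),
        n_fc=sum(not e.is_ic for e in events),
        knee_flexion_mean_waveform=knee.mean_waveform.tolist(),
        n_degenerate_frames=leg.n_degenerate + pitch.n_degenerate,
    )
    if baseline is None:
        result.foot_strike = "uncalibrated"
        result.warnings.append("no static calibration; foot strike not classified")
    else:
        result.baseline_foot_angle_deg = baseline.baseline_foot_angle
        devs = [s.foot_deviation_at_ic for s in strides]
        cls, mean_dev = classify_foot_strike(devs, config.footstrike.threshold_deg)
        result.foot_strike = cls
        result.mean_foot_deviation_deg = mean_dev
        result.per_strike_classes = [
            _classify_one(d, config.footstrike.threshold_deg) for d in devs
        ]
        if config.footstrike.velocity_check:
            result.warnings.append(_velocity_check_note(smoothed, side, strides))
    return result


def _velocity_check_note(series: KeypointSeries, side: str, strides) -> str:
    """Diagnostic cross-check: is the toe moving downward relative to the heel
    at impact? Reported as a note, never used for the primary class."""
    from .io import landmark

    toe_y = series.xy(landmark(side, "toe"))[:, 1]
    heel_y = series.xy(landmark(side, "heel"))[:, 1]
    rel = toe_y - heel_y  # image coords: increasing = toe moving down vs heel
    n_down = 0
    for s in strides:
        f = s.ic_frame
        if 1 <= f < len(rel):
            n_down += rel[f] - rel[f - 1] > 0
    return (
        f"velocity check: toe moving down relative to heel at "
        f"{n_down}/{len(strides)} initial contacts"
    )


def analyze_session(
    series: KeypointSeries,
    static_series: Optional[KeypointSeries] = None,
    config: AnalysisConfig = AnalysisConfig(),
    sides: Sequence[str] = SIDES,
) -> SessionResult:
    """Run the full per-side pipeline and assemble a session result.

    A side that fails (occlusion-corrupted data, too few events, unstable
    calibration) is reported with its reason without aborting the other
    side; the session fails only when every side does.
    """
    smoothed = smooth_series(series, config.smoothing)
    result = SessionResult(
        fps=series.fps,
        duration_s=series.duration_s,
        cadence_spm=0.0,
        config=config.echo(),
    )
    events_by_side: dict = {}
    for side in sides:
        if side in series.failed_sides:
            result.sides[side] = SideResult(error=series.failed_sides[side])
            continue
        baseline = None
        baseline_note = None
        if static_series is not None:
            try:
                baseline = calibrate_baseline(
                    static_series, side, config.footstrike, config.smoothing
                )
            except GaitposeError as exc:
                baseline_note = f"calibration failed: {exc}"
        try:
            side_result = _analyze_side(smoothed, side, baseline, config)
        except GaitposeError as exc:
            result.sides[side] = SideResult(error=str(exc))
            continue
        if baseline_note:
            side_result.foot_strike = "uncalibrated"
            side_result.warnings.append(baseline_note)
        result.sides[side] = side_result
        events_by_side[side] = side_result

    if all(r.error is not None for r in result.sides.values()):
        raise SessionError({s: r.error for s, r in result.sides.items()})

    def _events_as_ic_count(side_result: Optional[SideResult]):
        return side_result.n_ic if side_result and side_result.error is None else 0

    n_ic = sum(_events_as_ic_count(result.sides.get(s)) for s in sides)
    result.cadence_spm = n_ic / series.duration_s * 60.0 if n_ic else 0.0
    if n_ic == 0:
        result.warnings.append("no initial contacts detected; cadence is 0")
    return result
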