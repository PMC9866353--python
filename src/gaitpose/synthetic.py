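"""Synthetic side-view running-gait keypoint generator with exact ground truth.

The generator works angle-first: it programs the per-frame leg-extension and
foot-pitch angle traces directly from gait parameters (cadence, duty factor,
event-phase knot angles) and then *inverts* the geometry to place hip, knee,
ankle, heel and toe keypoints that reproduce those angles exactly. This
guarantees exact ground truth for every quantity the pipeline estimates —
event frames, contact/swing/step times, knee-flexion minima, foot-strike
deviations — which forward biomechanical simulation could not.

The leg-extension waveform honors the signal structure the detector assumes:
two above-threshold peaks per stride (at initial and final contact), a deep
minimum before IC (swing-phase knee flexion, default 90 deg) and a shallower
dip before FC (mid-stance, default 150 deg), joined by monotone cubic (PCHIP)
segments so the gradient has no spurious zero-crossings.

Conventions: image coordinates (y down), pixels; the runner faces +x; the
right side lags the left by half the same-foot period (one step). A static
standing segment (for foot-pitch calibration) is prepended to the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import ConfigurationError, ContractError
from .io import SIDES, KeypointSeries, landmark

#: IC foot-pitch deviation from baseline programmed per strike class (degrees)
STRIKE_DEVIATIONS = {"forefoot": 8.0, "midfoot": 0.0, "rearfoot": -8.0}


@dataclass(frozen=True)
class SyntheticGaitConfig:
    """Study conditions for one simulated bout.

    Defaults reproduce a typical treadmill protocol: 240 fps slow-motion
    capture, 60 s bouts, cadence 170 steps/min, duty factor (CT/StT) 0.34,
    preceded by a 2 s standing calibration.
    """

    fps: float = 240.0
    duration_s: float = 60.0
    cadence_spm: float = 170.0
    duty_factor: float = 0.34
    swing_min_deg: float = 90.0  # deep pre-IC minimum (max knee flexion in swing)
    stance_dip_deg: float = 150.0  # shallow pre-FC minimum (mid-stance)
    peak_deg: float = 172.0  # leg extension at IC and FC
    thigh_px: float = 180.0
    shank_px: float = 170.0
    foot_px: float = 80.0
    hip_osc_px: float = 10.0
    baseline_foot_deg: float = 90.0
    strike_class_left: str = "rearfoot"
    strike_class_right: str = "rearfoot"
    pushoff_deg: float = 35.0  # plantarflexion above baseline at toe-off
    noise_sd_px: float = 0.0
    right_noise_multiplier: float = 1.0  # occlusion mimic for the camera-far side
    stride_time_jitter_cv: float = 0.0  # per-stride step-time CV (0 = strictly periodic)
    static_calibration_s: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.duty_factor < 1):
            raise ConfigurationError("duty_factor must be in (0, 1)")
        if not (self.swing_min_deg < self.stance_dip_deg < self.peak_deg <= 180.0):
            raise ConfigurationError(
                "require swing_min_deg < stance_dip_deg < peak_deg <= 180"
            )
        if min(self.thigh_px, self.shank_px, self.foot_px) <= 0:
            raise ConfigurationError("segment lengths must be positive")
        if self.fps <= 0 or self.duration_s <= 0 or self.cadence_spm <= 0:
            raise ConfigurationError("fps, duration_s and cadence_spm must be positive")
        for cls in (self.strike_class_left, self.strike_class_right):
            if cls not in STRIKE_DEVIATIONS:
                raise ConfigurationError(f"unknown strike class {cls!r}")
        if not (0 < self.baseline_foot_deg + STRIKE_DEVIATIONS[self.strike_class_left] < 180):
            raise ConfigurationError("infeasible foot geometry for left strike class")

    @property
    def step_time_s(self) -> float:
        """Same-foot IC-to-IC period (two steps of the combined cadence)."""
        return 120.0 / self.cadence_spm

    def strike_class(self, side: str) -> str:
        return self.strike_class_left if side == "left" else self.strike_class_right


@dataclass
class SideTruth:
    ic_frames: np.ndarray
    fc_frames: np.ndarray
    contact_times: np.ndarray  # s, per stride (IC_x .. FC_x)
    swing_times: np.ndarray
    step_times: np.ndarray
    knee_flexion_min: float  # programmed swing minimum, degrees
    deviation_at_ic: float  # programmed IC foot-pitch deviation, degrees
    strike_class: str
    leg_extension: np.ndarray = field(repr=False, default=None)  # programmed trace
    foot_pitch: np.ndarray = field(repr=False, default=None)


@dataclass
class GroundTruth:
    """Everything the generator programmed, frame-indexed on the run segment."""

    fps: float
    n_calibration_frames: int
    n_run_frames: int
    cadence_spm: float
    duty_factor: float
    baseline_foot_angle: float
    sides: dict  # side -> SideTruth


def _leg_extension_knots(cfg: SyntheticGaitConfig, tics: np.ndarray):
    """(time, angle) knots, one block per stride period between consecutive ICs.

    Peak extension is momentary (as in real leg-extension traces): shoulder
    knots keep the signal near the mid-stance dip through most of stance and
    near the swing minimum through most of swing, so the two contact peaks
    stand clearly above the 90th-percentile (and 90%-of-max) threshold.
    """
    dip_shoulder = cfg.stance_dip_deg + 0.2 * (cfg.peak_deg - cfg.stance_dip_deg)
    swing_shoulder = cfg.swing_min_deg + 0.35 * (cfg.peak_deg - cfg.swing_min_deg)
    times, angles = [], []
    for k in range(len(tics) - 1):
        tic = tics[k]
        ct = cfg.duty_factor * (tics[k + 1] - tics[k])
        st = (tics[k + 1] - tics[k]) - ct
        times += [
            tic,
            tic + 0.15 * ct,
            tic + 0.5 * ct,
            tic + 0.85 * ct,
            tic + ct,
            tic + ct + 0.2 * st,
            tic + ct + 0.6 * st,
            tic + ct + 0.85 * st,
        ]
        angles += [
            cfg.peak_deg,
            dip_shoulder,
            cfg.stance_dip_deg,
            dip_shoulder,
            cfg.peak_deg,
            swing_shoulder,
            cfg.swing_min_deg,
            swing_shoulder,
        ]
    return np.array(times), np.array(angles)


def _foot_pitch_knots(cfg: SyntheticGaitConfig, tics: np.ndarray, dev: float):
    """Foot-pitch knots: strike plateau around IC, flat mid-stance, push-off at FC."""
    base = cfg.baseline_foot_deg
    times, angles = [], []
    for k in range(len(tics) - 1):
        tic = tics[k]
        ct = cfg.duty_factor * (tics[k + 1] - tics[k])
        st = (tics[k + 1] - tics[k]) - ct
        times += [tic - 0.05, tic, tic + 0.03, tic + 0.5 * ct, tic + ct, tic + ct + 0.4 * st]
        angles += [base + dev, base + dev, base + dev, base, base + cfg.pushoff_deg, base + 5.0]
    return np.array(times), np.array(angles)


def _realize_side(cfg: SyntheticGaitConfig, t: np.ndarray, theta_deg: np.ndarray,
                  psi_deg: np.ndarray, t_first_ic: float) -> dict:
    """Place keypoints reproducing the programmed angles exactly."""
    T = cfg.step_time_s
    phase = 2 * np.pi * (t - t_first_ic) / T
    hip = np.column_stack([
        np.full_like(t, 960.0),
        540.0 + cfg.hip_osc_px * np.sin(2 * phase),
    ])
    # thigh orientation from vertical-down, smooth sinusoid (forward at IC)
    phi = np.radians(25.0 * np.cos(phase))
    knee = hip + cfg.thigh_px * np.column_stack([np.sin(phi), np.cos(phi)])
    # rotate the knee->hip unit vector by theta to place the ankle
    u = (hip - knee) / cfg.thigh_px
    th = np.radians(theta_deg)
    c, s = np.cos(th), np.sin(th)
    rot = np.column_stack([c * u[:, 0] - s * u[:, 1], s * u[:, 0] + c * u[:, 1]])
    ankle = knee + cfg.shank_px * rot
    heel = ankle.copy()
    psi = np.radians(psi_deg)
    toe = heel + cfg.foot_px * np.column_stack([np.sin(psi), -np.cos(psi)])
    return {"hip": hip, "knee": knee, "ankle": ankle, "heel": heel, "toe": toe}


def _static_side(cfg: SyntheticGaitConfig, n: int) -> dict:
    ones = np.ones(n)
    theta = np.full(n, 175.0)
    psi = np.full(n, cfg.baseline_foot_deg)
    t = np.zeros(n)
    out = _realize_side(cfg, t, theta, psi, t_first_ic=0.0)
    # freeze the standing pose: take frame 0 of the dynamic construction
    return {k: np.outer(ones, v[0]) for k, v in out.items()}


def simulate(config: SyntheticGaitConfig) -> tuple:
    """Generate a keypoint series (static calibration + run) and its ground truth."""
    cfg = config
    fps = cfg.fps
    n_run = int(round(cfg.duration_s * fps))
    n_cal = int(round(cfg.static_calibration_s * fps))
    t = np.arange(n_run) / fps
    T = cfg.step_time_s
    n_periods = int(np.ceil(cfg.duration_s / T)) + 1

    rng = np.random.default_rng(cfg.seed)
    # IC times: strictly periodic by default, with optional stride-to-stride
    # step-time jitter; periods start two strides before the bout so the
    # waveform is well-defined from frame 0. The first in-bout IC falls half
    # a step-time in (the bout starts mid-swing) so the first peak's
    # lookback window is complete; the right side lags by one step.
    n_periods_total = n_periods + 5  # covers k = -2 .. n_periods + 2
    durations = np.full(n_periods_total + 1, T)
    cv = cfg.stride_time_jitter_cv
    if cv > 0:
        durations = durations * (
            1.0 + np.clip(cv * rng.standard_normal(len(durations)), -3 * cv, 3 * cv)
        )
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    tics_left = T / 2 + starts - starts[2]

    coords: dict = {}
    truth_sides: dict = {}
    for side in SIDES:
        tics = tics_left + (T / 2 if side == "right" else 0.0)
        dev = STRIKE_DEVIATIONS[cfg.strike_class(side)]
        kt, ka = _leg_extension_knots(cfg, tics)
        theta = PchipInterpolator(kt, ka)(t)
        ft, fa = _foot_pitch_knots(cfg, tics, dev)
        psi = PchipInterpolator(ft, fa)(t)

        pts = _realize_side(cfg, t, theta, psi, tics[2])
        static_pts = _static_side(cfg, n_cal)
        for role, arr in pts.items():
            coords[landmark(side, role)] = np.vstack([static_pts[role], arr])

        ic_t = tics[1:-1]
        fc_t = ic_t + cfg.duty_factor * (tics[2:] - tics[1:-1])
        in_bout = ic_t >= 0
        ic_t, fc_t = ic_t[in_bout], fc_t[in_bout]
        ic_frames = np.round(ic_t * fps).astype(int)
        fc_frames = np.round(fc_t * fps).astype(int)
        keep_ic = ic_frames < n_run
        keep_fc = fc_frames < n_run
        ic_frames, fc_frames = ic_frames[keep_ic], fc_frames[keep_fc]
        n_strides = min(len(ic_frames), len(fc_frames))
        cts = (fc_frames[:n_strides] - ic_frames[:n_strides]) / fps
        n_full = min(n_strides, len(ic_frames) - 1)
        sts = (ic_frames[1:n_full + 1] - fc_frames[:n_full]) / fps
        stts = (ic_frames[1:n_full + 1] - ic_frames[:n_full]) / fps
        truth_sides[side] = SideTruth(
            ic_frames=ic_frames,
            fc_frames=fc_frames,
            contact_times=cts,
            swing_times=sts,
            step_times=stts,
            knee_flexion_min=cfg.swing_min_deg,
            deviation_at_ic=dev,
            strike_class=cfg.strike_class(side),
            leg_extension=theta,
            foot_pitch=psi,
        )

    if cfg.noise_sd_px > 0:
        for name in list(coords):
            sd = cfg.noise_sd_px * (
                cfg.right_noise_multiplier if name.startswith("right") else 1.0
            )
            coords[name] = coords[name] + rng.normal(0.0, sd, coords[name].shape)

    series = KeypointSeries(fps=fps, coords=coords)
    truth = GroundTruth(
        fps=fps,
        n_calibration_frames=n_cal,
        n_run_frames=n_run,
        cadence_spm=cfg.cadence_spm,
        duty_factor=cfg.duty_factor,
        baseline_foot_angle=cfg.baseline_foot_deg,
        sides=truth_sides,
    )
    return series, truth


def split_calibration(series: KeypointSeries, truth: GroundTruth) -> tuple:
    """Split a simulated series into (static_segment, run_segment)."""
    n = truth.n_calibration_frames
    return series.slice(0, n), series.slice(n, None)


def session_from_truth(truth: GroundTruth) -> "SessionResult":
    """Render programmed ground truth as a reference SessionResult stream,
    suitable for agreement analysis against pipeline output."""
    from .io import SessionResult, SideResult
    from .outcomes import StrideMetrics

    result = SessionResult(
        fps=truth.fps,
        duration_s=truth.n_run_frames / truth.fps,
        cadence_spm=truth.cadence_spm,
        config={"source": "synthetic ground truth"},
    )
    for side, st in truth.sides.items():
        strides = []
        n = len(st.contact_times)
        for x in range(n):
            strides.append(
                StrideMetrics(
                    stride_index=x,
                    side=side,
                    ic_frame=int(st.ic_frames[x]),
                    fc_frame=int(st.fc_frames[x]),
                    next_ic_frame=int(st.ic_frames[x + 1]) if x + 1 < len(st.ic_frames) else None,
                    contact_time=float(st.contact_times[x]),
                    swing_time=float(st.swing_times[x]) if x < len(st.swing_times) else None,
                    step_time=float(st.step_times[x]) if x < len(st.step_times) else None,
                    knee_flexion_min=st.knee_flexion_min,
                    foot_angle_at_ic=truth.baseline_foot_angle + st.deviation_at_ic,
                    foot_deviation_at_ic=st.deviation_at_ic,
                )
            )
        result.sides[side] = SideResult(
            strides=strides,
            n_ic=len(st.ic_frames),
            n_fc=len(st.fc_frames),
            foot_strike=st.strike_class,
            mean_foot_deviation_deg=st.deviation_at_ic,
            baseline_foot_angle_deg=truth.baseline_foot_angle,
        )
    return result


def perturb_occlusion(
    series: KeypointSeries,
    side: str,
    sd_px: float,
    seed: int,
    ic_frames: Optional[np.ndarray] = None,
    burst_rate_hz: float = 1.0,
) -> KeypointSeries:
    """Add burst noise to one side's landmarks, mimicking leg-on-leg occlusion.

    Random 0.1-0.3 s windows receive additive Gaussian noise; when
    ``ic_frames`` is given the bursts are centered mid-stride (halfway
    between consecutive ICs, where occlusion by the near leg occurs),
    otherwise burst centers are uniform over the bout.
    """
    if side not in SIDES:
        raise ContractError(f"unknown side {side!r}")
    out = series.slice(0, None)
    if sd_px <= 0:
        return out
    rng = np.random.default_rng(seed)
    n = series.n_frames
    fps = series.fps
    if ic_frames is not None and len(ic_frames) > 1:
        centers = ((np.asarray(ic_frames)[:-1] + np.asarray(ic_frames)[1:]) // 2).astype(int)
    else:
        n_bursts = max(1, int(round(series.duration_s * burst_rate_hz)))
        centers = rng.integers(0, n, size=n_bursts)
    mask = np.zeros(n, dtype=bool)
    for c in centers:
        half = int(round(rng.uniform(0.05, 0.15) * fps))
        mask[max(0, c - half): min(n, c + half)] = True
    idx = np.flatnonzero(mask)
    for name in out.coords:
        if name.startswith(side):
            out.coords[name][idx] += rng.normal(0.0, sd_px, (len(idx), 2))
    return out
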