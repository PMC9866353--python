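# Methods

This note states the definitions, algorithms and conventions implemented by
`gaitpose`, in pipeline order. All angles are in degrees, all times in
seconds, and all image coordinates are pixels with the y-axis pointing down.

## 1. Input and repair (`gaitpose.io`)

A session is a time series of ten landmarks — hip, knee, ankle, heel, toe
for each side — at a known frame rate (default protocol: 240 fps slow-motion
capture). Frames must be consecutive. If per-landmark visibility scores are
supplied, coordinates with visibility < 0.1 are treated as missing and
linearly interpolated across gaps of up to 5 frames; a longer gap marks that
body side as failed while the other side proceeds.

## 2. Smoothing (`gaitpose.preprocess`)

Every coordinate stream is smoothed with a 5-frame centered moving average
before any angle computation. Edges use a shrinking window by default
(average over the in-bounds samples), so the output has the input's length
and a centered window introduces no phase lag into event frames. A mirrored
("reflect") edge mode and a trailing (causal) window are available for
sensitivity analysis.

## 3. Joint angles (`gaitpose.kinematics`)

The angle at vertex `v` between points `a` and `b` is

```
θ = arccos( (a−v)·(b−v) / (‖a−v‖ ‖b−v‖) ) ∈ [0°, 180°]
```

* **Leg-extension angle**: hip–knee–ankle. 180° is a straight leg; the angle
  falls as the knee flexes. This is the event-detection signal.
* **Foot-pitch angle**: the angle at the heel between the heel→toe ray and
  the vertical reference `vH = heel + (0, −1)` (straight up in image
  coordinates). A toe level with the heel gives 90°; raising the toe above
  the heel decreases the angle.

A frame where either ray has zero length is degenerate: the previous frame's
value is carried over and the count of such frames is reported. A degenerate
first frame is an error.

## 4. Event detection (`gaitpose.events`)

At both initial contact (IC, footstrike) and final contact (FC, toe-off) the
leg is near full extension, so both events appear as peaks of the smoothed
leg-extension angle. Detection:

1. **Dynamic threshold** — the 90th percentile of the smoothed signal
   (`percentile_90`, default) or 0.9 × its maximum (`fraction_of_max`). A
   flat signal (zero range) is a degenerate-signal error (e.g. standing).
2. **Peak picking** — strict local maxima above the threshold
   (`scipy.signal.find_peaks`, plateaus resolved to their midpoint); peaks
   closer than 0.05 s are merged keeping the higher one.
3. **IC/FC labelling by preceding-minimum depth** — for each peak, the
   signal minimum in the preceding 0.30 s (clipped at the previous peak) is
   computed. Before an IC the leg has just swung through (deep minimum,
   maximal swing knee flexion, ≈90° in the synthetic model); before an FC
   the leg has only dipped through mid-stance (shallow minimum, ≈150°). The
   minima are split into deep/shallow by one-dimensional two-means
   clustering; deep ⇒ IC, shallow ⇒ FC. A fixed minimum gap in degrees may
   be configured instead of the clustering boundary.
4. **Alternation repair** — labels must strictly alternate. When two equal
   labels are adjacent (a spurious or missed peak), the peak whose preceding
   minimum lies closest to the deep/shallow boundary — the least decisive
   one — is dropped and labelling is redone; each repair is counted as a
   warning. A first peak whose lookback window is truncated by the start of
   the recording is discarded.

Fewer than 4 labelled events is an insufficient-events error.

## 5. Temporal outcomes (`gaitpose.outcomes`)

With same-foot event sequences `IC_i … FC_i … IC_{i+1}` and frame rate `fps`:

* contact time `CT_i = (FC_i − IC_i) / fps`
* swing time `ST_i = (IC_{i+1} − FC_i) / fps`
* step time `StT_i = (IC_{i+1} − IC_i) / fps`, so `StT = CT + ST` holds
  exactly at the frame level
* cadence = (total IC count over both sides / analyzed duration) × 60, in
  steps/min.

Knee-flexion outcomes per stride: the leg-extension angle at IC, at FC, and
its minimum within the stride; plus the across-stride mean waveform resampled
to 101 points (0–100% of the stride).

## 6. Foot-strike classification

A standing-calibration segment (≥ 0.5 s; rejected if the smoothed foot-pitch
standard deviation exceeds 2°, i.e. the foot was moving) provides the
baseline foot angle. At each IC the deviation Δ = angle − baseline is
recorded; the session-level class is decided by the **mean** deviation:

* Δ > +5° → forefoot
* −5° ≤ Δ ≤ +5° → midfoot (closed interval)
* Δ < −5° → rearfoot

Without a calibration segment the session is reported as `uncalibrated` and
temporal outcomes are still produced. Analysis failures are isolated per
side; only if every requested side fails is the session an error.

## 7. Agreement statistics (`gaitpose.agreement`)

For validating the pipeline against a reference measurement, per-stride
streams are aligned by nearest IC frame within 0.1 s (one-to-one), then:

* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measures, from the two-way ANOVA mean squares with k = 2 raters:
  `ICC = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`. Undefined
  (error) when the between-subject variance is zero.
* **Pearson's r**, optionally on log10-transformed values (step time by
  default, whose raw distribution is right-skewed); NaN for a constant
  stream.
* **Mean error** — the mean absolute difference (the signed mean is reported
  alongside as the bias).
* **Bland–Altman** — bias ± 1.96 × SD of the differences (SD with ddof = 1),
  with per-pair (mean, difference) coordinates for plotting.

## 8. Synthetic generator (`gaitpose.synthetic`)

The generator is *angle-first*: it programs the per-frame leg-extension and
foot-pitch traces from gait parameters and inverts the geometry to place
keypoints, so ground truth is exact by construction.

* Per stride (same-foot period `T = 120/cadence` s), the leg-extension trace
  passes through knots: peak (default 172°) at IC, deep minimum (90°) before
  the next IC, peak at FC (`FC = IC + duty_factor · T`), shallow dip (150°)
  at mid-stance — joined by monotone cubic (PCHIP) segments, with shoulder
  knots keeping the trace well below threshold between events so that each
  stride yields exactly two above-threshold peaks under either threshold
  mode.
* The bout starts mid-swing (first IC at T/2) and the right side lags the
  left by one step (T/2). Optional per-stride timing jitter
  (`stride_time_jitter_cv`) makes the stride times vary around the mean.
* Foot pitch rests at the standing baseline (90°), deviates at IC by +8°/0°/
  −8° for forefoot/midfoot/rearfoot, and rises for push-off after FC.
* Gaussian pixel noise of configurable SD is added per keypoint; the right
  side can receive a noise multiplier to mimic occlusion of the camera-far
  leg, and `perturb_occlusion` adds mid-stride burst noise.
* A 2 s standing segment for calibration is prepended; `split_calibration`
  separates it from the run.

Ground-truth event frames are reported as `round(t · fps)`. Events within
0.30 s of the start (truncated lookback) or 0.05 s of the end (no descending
flank) of a bout are not recoverable in principle; evaluation against ground
truth therefore scores interior events.

## 9. Validation protocol (`scripts/acceptance.py`)

Four targets, recomputed from scratch on every run (bout `i` uses RNG seed
`base_seed · 1000 + i`; `--seed 0` gives the canonical seeds):

| id | experiment | statistic | pass |
|----|-----------|-----------|------|
| t1 | 10 × 60 s bouts, fps 240, cadence ~ U(160, 180), duty ~ U(0.30, 0.38), noise SD 2 px | pooled left-side CT/ST/StT mean absolute error vs ground truth | ≤ 0.014 s |
| t2 | same experiment | minimum per-outcome ICC(2,1), strides pooled over bouts | ≥ 0.75 |
| t3 | same experiment | mean absolute cadence error | ≤ 1.2 steps/min |
| t4 | 20 bouts, cadence 170, duty 0.34, noise SD 2 px, strike class ~ U{forefoot, midfoot, rearfoot} | left-side session-level classification accuracy | ≥ 95.2% |

`tests/test_acceptance.py` asserts these four targets plus clean-bout event
recovery (±2 frames, both threshold modes), oracle equivalence of the ICC
and angle implementations, and the exact identities (StT = CT + ST, rigid
-transform invariance, same-seed determinism).
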