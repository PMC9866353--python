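"""Coordinate-signal smoothing.

Pose-estimation keypoints jitter frame to frame, so every coordinate stream
is smoothed with a short moving average (default 5 frames) before any angle
or event computation. The window is centered by default so that smoothing
introduces no phase lag into the detected event frames; a trailing window is
available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError
from .io import KeypointSeries


@dataclass(frozen=True)
class SmoothingConfig:
    """Moving-average parameters.

    window : odd positive frame count (default 5).
    edge_mode : 'shrink' averages over the samples available near the edges;
        'reflect' mirror-pads the signal.
    centered : center the window on the current frame (default) or trail it.
    """

    window: int = 5
    edge_mode: str = "shrink"
    centered: bool = True

    def __post_init__(self):
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigurationError(
                f"smoothing window must be a positive odd integer, got {self.window}"
            )
        if self.edge_mode not in ("shrink", "reflect"):
            raise ConfigurationError(f"unknown edge_mode {self.edge_mode!r}")


def moving_average(signal, config: SmoothingConfig = SmoothingConfig()) -> np.ndarray:
    """Length-preserving moving average of a 1-D signal."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    w = config.window
    if w == 1 or len(x) == 0:
        return x.copy()
    kernel = np.ones(w)
    if config.centered:
        if config.edge_mode == "reflect":
            pad = w // 2
            padded = np.pad(x, pad, mode="reflect")
            return np.convolve(padded, kernel / w, mode="valid")
        # shrink: divide by the number of in-bounds samples at each position
        # (full convolution + centered slice also handles len(x) < window)
        half = (w - 1) // 2
        num = np.convolve(x, kernel, mode="full")[half: half + len(x)]
        den = np.convolve(np.ones_like(x), kernel, mode="full")[half: half + len(x)]
        return num / den
    # trailing window: current frame and the w-1 preceding frames
    if config.edge_mode == "reflect":
        padded = np.pad(x, (w - 1, 0), mode="reflect")
        return np.convolve(padded, kernel / w, mode="valid")
    csum = np.cumsum(np.concatenate(([0.0], x)))
    idx = np.arange(1, len(x) + 1)
    lo = np.maximum(idx - w, 0)
    return (csum[idx] - csum[lo]) / (idx - lo)


def smooth_series(
    series: KeypointSeries, config: SmoothingConfig = SmoothingConfig()
) -> KeypointSeries:
    """Apply :func:`moving_average` to every landmark's x and y stream."""
    coords = {}
    for name, xy in series.coords.items():
        coords[name] = np.column_stack(
            [moving_average(xy[:, 0], config), moving_average(xy[:, 1], config)]
        )
    return KeypointSeries(
        fps=series.fps,
        coords=coords,
        visibility=None if series.visibility is None else {k: v.copy() for k, v in series.visibility.items()},
        failed_sides=dict(series.failed_sides),
    )
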