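"""Method-agreement statistics for predicted-vs-reference outcome streams.

The validation toolbox used to compare pipeline output against a reference
measurement system:

* **ICC(2,1)** — intraclass correlation, two-way random effects, absolute
  agreement, single measures, from the two-way ANOVA mean squares
  (``MSR`` rows/subjects, ``MSC`` columns/raters, ``MSE`` residual)::

      ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),   k = 2

* **Pearson's r**, optionally on log10-transformed values for outcomes whose
  raw distribution is non-normal (step time by default);
* **mean error** — mean absolute difference (the signed mean is reported
  alongside);
* **Bland-Altman** bias and 95% limits of agreement (bias +/- 1.96 SD of the
  differences), with per-pair (mean, difference) coordinates for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ContractError
from .io import SessionResult

#: outcomes that get a log10 pre-transform before Pearson correlation
DEFAULT_LOG10_OUTCOMES = frozenset({"step_time"})


@dataclass
class PairedOutcomes:
    """Matched predicted/reference value pairs for one outcome."""

    predicted: np.ndarray
    reference: np.ndarray
    outcome_name: str = ""
    units: str = ""

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.predicted.shape != self.reference.shape or self.predicted.ndim != 1:
            raise ContractError("predicted and reference must be equal-length 1-D")
        if len(self.predicted) < 3:
            raise ContractError("need at least 3 pairs")
        if not (np.isfinite(self.predicted).all() and np.isfinite(self.reference).all()):
            raise ContractError("values must be finite")

    @property
    def n(self) -> int:
        return len(self.predicted)


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False, default=None)
    differences: np.ndarray = field(repr=False, default=None)


@dataclass
class AgreementStats:
    outcome_name: str
    units: str
    n: int
    mean_predicted: float
    mean_reference: float
    mean_error: float  # mean absolute error
    signed_mean_error: float
    icc_2_1: float
    pearson_r: float
    bland_altman: BlandAltman


def icc_2_1(pairs: PairedOutcomes) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures."""
    data = np.column_stack([pairs.predicted, pairs.reference])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.ptp(row_means) <= 0:
        raise ContractError(
            "ICC(2,1) undefined: zero between-subject variance"
        )
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse)))


def pearson(pairs: PairedOutcomes, log10_transform: bool = False) -> float:
    """Product-moment correlation, optionally on log10-transformed pairs."""
    x, y = pairs.predicted, pairs.reference
    if log10_transform:
        if (x <= 0).any() or (y <= 0).any():
            raise ContractError(
                f"log10 transform requires strictly positive values "
                f"({pairs.outcome_name or 'stream'})"
            )
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")  # correlation undefined for a constant stream
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(pairs: PairedOutcomes) -> BlandAltman:
    """Bias and 95% limits of agreement of predicted - reference."""
    d = pairs.predicted - pairs.reference
    m = (pairs.predicted + pairs.reference) / 2.0
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, m, d)


def compute_agreement(
    pairs: PairedOutcomes, log10_transform: bool = False
) -> AgreementStats:
    """All agreement statistics for one paired outcome stream."""
    d = pairs.predicted - pairs.reference
    return AgreementStats(
        outcome_name=pairs.outcome_name,
        units=pairs.units,
        n=pairs.n,
        mean_predicted=float(np.mean(pairs.predicted)),
        mean_reference=float(np.mean(pairs.reference)),
        mean_error=float(np.mean(np.abs(d))),
        signed_mean_error=float(np.mean(d)),
        icc_2_1=icc_2_1(pairs),
        pearson_r=pearson(pairs, log10_transform),
        bland_altman=bland_altman(pairs),
    )


# ---------------------------------------------------------------------------
# session comparison (Table-style report)
# ---------------------------------------------------------------------------

_TIME_OUTCOMES = (
    ("contact_time", "s"),
    ("swing_time", "s"),
    ("step_time", "s"),
)
_ANGLE_OUTCOMES = (
    ("knee_flexion_min", "deg"),
    ("foot_deviation_at_ic", "deg"),
)


def match_frames(detected: Sequence[int], reference: Sequence[int], tol: float):
    """One-to-one nearest matching of detected to reference frame indices.

    Returns (pairs, unmatched_reference) where pairs is a list of
    (detected_frame, reference_frame) with |difference| <= tol.
    """
    detected = np.asarray(detected, dtype=float)
    pairs, unmatched = [], []
    used = set()
    for r in reference:
        matched = False
        order = np.argsort(np.abs(detected - r)) if len(detected) else []
        for j in order:
            if j in used:
                continue
            if abs(detected[j] - r) <= tol:
                used.add(int(j))
                pairs.append((int(detected[j]), int(r)))
                matched = True
            break  # nearest unused candidate decides
        if not matched:
            unmatched.append(r)
    return pairs, unmatched


def _match_strides(pred_strides, ref_strides, fps: float, tol_s: float = 0.1):
    """Pair strides by nearest IC frame within ``tol_s``; one-to-one, in order."""
    tol = tol_s * fps
    ref_ics = np.array([s.ic_frame for s in ref_strides], dtype=float)
    pairs = []
    used = set()
    for p in pred_strides:
        if len(ref_ics) == 0:
            break
        j = int(np.argmin(np.abs(ref_ics - p.ic_frame)))
        if j in used or abs(ref_ics[j] - p.ic_frame) > tol:
            continue
        used.add(j)
        pairs.append((p, ref_strides[j]))
    return pairs


def compare_sessions(
    predicted: SessionResult,
    reference: SessionResult,
    *,
    log10_outcomes: frozenset = DEFAULT_LOG10_OUTCOMES,
    match_tol_s: float = 0.1,
) -> pd.DataFrame:
    """Per-side, per-outcome agreement table between two session results.

    Strides are aligned by nearest IC frame within ``match_tol_s``. Returns a
    DataFrame with one row per (side, outcome): means, mean (absolute and
    signed) error, ICC(2,1), Pearson r, Bland-Altman bias/limits, and the
    min/max of each stream for the angle outcomes.
    """
    if abs(predicted.fps - reference.fps) > 1e-9:
        raise AlignmentError(
            f"fps mismatch: predicted {predicted.fps}, reference {reference.fps}"
        )
    rows = []
    any_matched = False
    for side in sorted(set(predicted.sides) & set(reference.sides)):
        pside, rside = predicted.sides[side], reference.sides[side]
        if pside.error is not None or rside.error is not None:
            continue
        matched = _match_strides(pside.strides, rside.strides, predicted.fps, match_tol_s)
        if len(matched) < 3:
            continue
        any_matched = True
        for name, units in _TIME_OUTCOMES + _ANGLE_OUTCOMES:
            pv = np.array([getattr(p, name) for p, _ in matched], dtype=float)
            rv = np.array([getattr(r, name) for _, r in matched], dtype=float)
            ok = np.isfinite(pv) & np.isfinite(rv)
            if ok.sum() < 3:
                continue
            pairs = PairedOutcomes(pv[ok], rv[ok], outcome_name=name, units=units)
            st = compute_agreement(pairs, log10_transform=name in log10_outcomes)
            rows.append(
                {
                    "side": side,
                    "outcome": name,
                    "units": units,
                    "n": st.n,
                    "mean_predicted": st.mean_predicted,
                    "mean_reference": st.mean_reference,
                    "min_predicted": float(pv[ok].min()),
                    "max_predicted": float(pv[ok].max()),
                    "min_reference": float(rv[ok].min()),
                    "max_reference": float(rv[ok].max()),
                    "mean_error": st.mean_error,
                    "signed_mean_error": st.signed_mean_error,
                    "icc_2_1": st.icc_2_1,
                    "pearson_r": st.pearson_r,
                    "ba_bias": st.bland_altman.bias,
                    "ba_loa_low": st.bland_altman.loa_low,
                    "ba_loa_high": st.bland_altman.loa_high,
                }
            )
    if not any_matched:
        n_p = sum(len(s.strides) for s in predicted.sides.values())
        n_r = sum(len(s.strides) for s in reference.sides.values())
        raise AlignmentError(
            f"no side could be aligned (predicted strides: {n_p}, "
            f"reference strides: {n_r}, tolerance {match_tol_s} s)"
        )
    return pd.DataFrame(rows)


def bland_altman_figure(pairs: PairedOutcomes, ax=None):
    """Bland-Altman scatter with bias and 95% limits of agreement."""
    import matplotlib.pyplot as plt

    ba = bland_altman(pairs)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ba.means, ba.differences, s=12, alpha=0.6)
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel(f"mean of methods ({pairs.units})")
    ax.set_ylabel(f"difference ({pairs.units})")
    ax.set_title(pairs.outcome_name or "Bland-Altman")
    return ax
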