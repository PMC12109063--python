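"""Median-frequency drift model and the N-level fatigue estimator.

The per-window median frequencies of one session are fitted with a line

    y = A·x + b

whose intercept b is the session's initial median frequency mf0 and whose
value at the last window center is the terminal median frequency mfS. The
absolute Pearson correlation R measures how well the line tracks the MF
distribution.

Per subject (and load), the intercepts and terminal values of the training
sessions are averaged into a standardized MF distribution range
[MF̄0, MF̄s] — the span from no fatigue to complete fatigue. That span is
split into N contiguous intervals of width Δ = (MF̄0 − MF̄s)/(N − 1),
centered on MF̄0 − k·Δ for level index k = 0 … N−1; a fitted MF value y_i
is assigned the level whose interval contains it, and the reported fatigue
level is LF = k/(N − 1) ∈ [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError, InsufficientDataError, NoFatigueRangeError, ParameterError
from .spectral import MFSeries

__all__ = [
    "LinearFit",
    "SMFDR",
    "FatigueEstimate",
    "fit_mf_line",
    "build_smfdr",
    "level_boundaries",
    "estimate_level",
    "fatigue_trajectory",
]


@dataclass(frozen=True)
class LinearFit:
    """Least-squares line through one session's MF series."""

    slope_A: float  # Hz/s
    intercept_b: float  # Hz; the initial median frequency mf0
    mf_S: float  # Hz; fitted value at the last window center
    R: float  # |Pearson correlation|, in [0, 1]
    t_end: float  # s, last window center
    n_windows: int
    degenerate: bool = False  # True when the MF series had zero variance


@dataclass(frozen=True)
class SMFDR:
    """Standardized median-frequency distribution range for one subject/load."""

    mf0_bar: float  # Hz, mean initial MF over the training set
    mfs_bar: float  # Hz, mean terminal MF over the training set
    n_train: int
    subject_id: str = ""
    load_label: str = ""

    @property
    def usable(self) -> bool:
        """A fatigue range exists only if MF̄0 exceeds MF̄s."""
        return self.mf0_bar > self.mfs_bar

    def require_usable(self) -> None:
        if not self.usable:
            raise NoFatigueRangeError(
                f"no fatigue range: mf0_bar={self.mf0_bar:.3f} <= "
                f"mfs_bar={self.mfs_bar:.3f}"
            )


@dataclass(frozen=True)
class FatigueEstimate:
    """Quantized fatigue level for one fitted MF value."""

    y_i: float  # Hz
    level_index_k: int  # 0 (no fatigue) … N−1 (complete fatigue)
    LF: float  # k/(N−1) ∈ [0, 1]
    N: int
    delta: float  # Hz, level width


def fit_mf_line(series: MFSeries) -> LinearFit:
    """Ordinary least squares of MF on window-center time.

    R is reported as the absolute Pearson correlation (fatigue slopes are
    negative; the magnitude measures fit consistency). A zero-variance MF
    series yields slope 0, R = 0 and the `degenerate` flag.
    """
    t, y = series.times, series.mf
    if t.size < 3:
        raise InsufficientDataError(f"need at least 3 windows to fit, got {t.size}")
    if not np.all(np.isfinite(y)):
        raise InputError("MF series contains non-finite values")

    t_end = float(t[-1])
    if float(np.var(y)) == 0.0:
        b = float(y[0])
        return LinearFit(0.0, b, b, 0.0, t_end, t.size, degenerate=True)

    slope, intercept = np.polyfit(t, y, 1)
    r = float(abs(np.corrcoef(t, y)[0, 1]))
    mf_s = float(slope * t_end + intercept)
    return LinearFit(float(slope), float(intercept), mf_s, r, t_end, t.size)


def build_smfdr(
    fits: list[LinearFit], subject_id: str = "", load_label: str = ""
) -> SMFDR:
    """Average training-session intercepts and terminal values into an SMFDR.

    An SMFDR with mf0_bar <= mfs_bar is returned flagged unusable (its
    `usable` property is False); the estimator refuses it.
    """
    if not fits:
        raise InsufficientDataError("SMFDR needs at least one training fit")
    mf0 = float(np.mean([f.intercept_b for f in fits]))
    mfs = float(np.mean([f.mf_S for f in fits]))
    return SMFDR(mf0_bar=mf0, mfs_bar=mfs, n_train=len(fits),
                 subject_id=subject_id, load_label=load_label)


def level_width(smfdr: SMFDR, N: int) -> float:
    """Δ = (MF̄0 − MF̄s)/(N − 1), the width of one fatigue level in Hz."""
    if N < 2:
        raise ParameterError(f"need at least 2 fatigue levels, got N={N}")
    smfdr.require_usable()
    return (smfdr.mf0_bar - smfdr.mfs_bar) / (N - 1)


def level_boundaries(smfdr: SMFDR, N: int) -> list[tuple[float, float, int]]:
    """The N half-open intervals ``(lo, hi], k`` of the fatigue quantizer.

    Interval k is (MF̄0 − (2k+1)Δ/2, MF̄0 − (2k−1)Δ/2], centered on
    MF̄0 − k·Δ; the centers run from MF̄0 (k=0) down to MF̄s (k=N−1) and
    the intervals tile the range with no gaps or overlaps.
    """
    delta = level_width(smfdr, N)
    out = []
    for k in range(N):
        hi = smfdr.mf0_bar - (2 * k - 1) * delta / 2.0
        lo = smfdr.mf0_bar - (2 * k + 1) * delta / 2.0
        out.append((lo, hi, k))
    return out


def estimate_level(
    y_i: float, smfdr: SMFDR, N: int, printed_clamp: bool = False
) -> FatigueEstimate:
    """Quantize a fitted MF value into one of N fatigue levels.

    Values above the no-fatigue interval clamp to k = 0 and values below
    the full-fatigue interval clamp to k = N−1. A value exactly on an
    interval edge belongs to the lower-frequency (more fatigued) interval.
    `printed_clamp` inverts the out-of-range branches (below the range → 0,
    above → N−1), kept for audit/comparison; it is not physiologically
    coherent and is off by default.
    """
    if not math.isfinite(y_i):
        raise InputError(f"fitted MF must be finite, got {y_i}")
    delta = level_width(smfdr, N)
    k = None
    for lo, hi, kk in level_boundaries(smfdr, N):
        if lo < y_i <= hi:
            k = kk
            break
    if k is None:  # outside the tiled range
        above = y_i > smfdr.mf0_bar
        if printed_clamp:
            # inverted orientation (below range → no fatigue, above → full)
            k = 0 if y_i < smfdr.mf0_bar else N - 1
        else:
            k = 0 if above else N - 1
    return FatigueEstimate(y_i=float(y_i), level_index_k=k, LF=k / (N - 1), N=N, delta=delta)


def fatigue_trajectory(
    fit: LinearFit, smfdr: SMFDR, N: int, times: np.ndarray
) -> list[FatigueEstimate]:
    """Fatigue level over time from a fitted MF line.

    Evaluates y = A·t + b at each query time and quantizes. For a
    fatiguing session (negative slope) the LF sequence is non-decreasing.
    """
    times = np.asarray(times, dtype=float)
    return [
        estimate_level(fit.slope_A * t + fit.intercept_b, smfdr, N) for t in times
    ]
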