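"""Windowed power spectra and median-frequency (MF) tracking.

The fatigue-sensitive observable is the median frequency — the frequency
splitting the power spectral density p(f) into equal-energy halves:

    ∫_0^MF p(f) df = ∫_MF^∞ p(f) df = ½ ∫_0^∞ p(f) df

MF is evaluated per analysis window on the high-frequency component of the
signal. Windows are long (10,240 ms by default) for frequency resolution,
stepped by 2,560 ms for temporal granularity; each window gets a single
Hann-tapered, mean-detrended periodogram (Welch sub-averaging is available
as an option). The half-energy point is located by linear interpolation on
the cumulative (trapezoid) spectral energy, so MF is not quantized to the
frequency grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, signal

from .errors import DegenerateSpectrumError, InputError, InputTooShortError
from .trace import SignalTrace

__all__ = [
    "Spectrum",
    "MFSeries",
    "window_segments",
    "psd",
    "median_frequency",
    "mf_series",
    "spectral_shift",
]

DEFAULT_WINDOW_MS = 10240.0
DEFAULT_STEP_MS = 2560.0


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # PSD, >= 0

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise InputError("freqs and power must be 1-D arrays of equal length")
        if np.any(np.diff(f) <= 0):
            raise InputError("freqs must be strictly increasing")
        if np.any(p < 0):
            raise InputError("power must be non-negative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)

    @property
    def total_power(self) -> float:
        """Integral of the PSD over the frequency axis (trapezoid rule)."""
        return float(np.trapezoid(self.power, self.freqs))

    @property
    def degenerate(self) -> bool:
        return self.total_power <= 0.0


@dataclass(frozen=True)
class MFSeries:
    """Per-window median frequencies with window-center times."""

    times: np.ndarray  # s, window centers, strictly increasing
    mf: np.ndarray  # Hz
    window_ms: float
    step_ms: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.mf, dtype=float)
        if t.shape != m.shape or t.ndim != 1:
            raise InputError("times and mf must be 1-D arrays of equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise InputError("window-center times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "mf", m)

    @property
    def n_windows(self) -> int:
        return self.times.size


def window_segments(
    trace: SignalTrace,
    window_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
) -> list[tuple[float, np.ndarray]]:
    """Cut a trace into fixed-length windows.

    Returns ``[(center_time_s, samples), ...]`` with
    ``count = floor((len_ms − window_ms)/step_ms) + 1``; trailing samples
    that do not fill a window are dropped (padding would bias the terminal
    MF that anchors the fatigue range).
    """
    win = int(round(window_ms * trace.fs / 1000.0))
    step = int(round(step_ms * trace.fs / 1000.0))
    if win < 2 or step < 1:
        raise InputError(f"window/step too small: {window_ms} ms / {step_ms} ms")
    if trace.n < win:
        raise InputTooShortError(
            f"trace of {trace.n / trace.fs * 1000:.0f} ms is shorter than one "
            f"{window_ms:.0f} ms window"
        )
    count = (trace.n - win) // step + 1
    out = []
    for k in range(count):
        start = k * step
        center = trace.t0 + (start + win / 2.0) / trace.fs
        out.append((center, trace.samples[start : start + win]))
    return out


def psd(
    segment: np.ndarray,
    fs: float,
    welch_nperseg: int | None = None,
) -> Spectrum:
    """One-sided PSD of a segment (Hann taper, mean detrend).

    By default a single tapered periodogram spans the whole segment; pass
    `welch_nperseg` to sub-average Welch style instead.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 16:
        raise InputTooShortError(f"PSD needs at least 16 samples, got {x.size}")
    if welch_nperseg is not None:
        f, p = signal.welch(x, fs=fs, window="hann", nperseg=welch_nperseg, detrend="constant")
    else:
        f, p = signal.periodogram(x, fs=fs, window="hann", detrend="constant")
    return Spectrum(freqs=f, power=p)


def median_frequency(spec: Spectrum) -> float:
    """Half-energy frequency of a spectrum.

    The cumulative energy is the trapezoid integral of p(f); the half-total
    crossing is located by linear interpolation between grid points.
    """
    cum = integrate.cumulative_trapezoid(spec.power, spec.freqs, initial=0.0)
    total = cum[-1]
    if total <= 0:
        raise DegenerateSpectrumError("spectrum carries no power; MF undefined")
    half = total / 2.0
    i = int(np.searchsorted(cum, half))
    if i == 0:
        return float(spec.freqs[0])
    f0, f1 = spec.freqs[i - 1], spec.freqs[i]
    c0, c1 = cum[i - 1], cum[i]
    if c1 == c0:
        return float(f0)
    return float(f0 + (f1 - f0) * (half - c0) / (c1 - c0))


def mf_series(
    imf1: np.ndarray | SignalTrace,
    fs: float | None = None,
    window_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
    t0: float = 0.0,
    welch_nperseg: int | None = None,
) -> MFSeries:
    """Median frequency of each analysis window of a (high-frequency) series."""
    if isinstance(imf1, SignalTrace):
        tr = imf1
    else:
        if fs is None:
            raise InputError("fs is required when imf1 is a bare array")
        tr = SignalTrace(imf1, fs, t0)
    segs = window_segments(tr, window_ms=window_ms, step_ms=step_ms)
    times = np.array([c for c, _ in segs])
    mfs = np.array(
        [median_frequency(psd(s, tr.fs, welch_nperseg=welch_nperseg)) for _, s in segs]
    )
    return MFSeries(times=times, mf=mfs, window_ms=window_ms, step_ms=step_ms)


def _unit_area(spec: Spectrum) -> Spectrum:
    return Spectrum(spec.freqs, spec.power / spec.total_power)


def _fraction_below(spec: Spectrum, split_hz: float) -> float:
    cum = integrate.cumulative_trapezoid(spec.power, spec.freqs, initial=0.0)
    return float(np.interp(split_hz, spec.freqs, cum) / cum[-1])


def spectral_shift(
    trace: SignalTrace,
    cycle_s: float = 4.0,
    n_cycles: int = 2,
    split_hz: float = 60.0,
) -> tuple[Spectrum, Spectrum, float]:
    """Compare the spectra of the first and last few contraction cycles.

    Returns unit-area spectra of the first and last ``n_cycles * cycle_s``
    seconds plus the change in the fraction of power below `split_hz`
    (last minus first); fatigue moves power down-band, making it positive.
    """
    seg_len = int(round(n_cycles * cycle_s * trace.fs))
    if trace.n < 2 * seg_len:
        raise InputTooShortError(
            f"need at least {2 * n_cycles * cycle_s:.0f} s of signal, have "
            f"{trace.duration_s:.1f} s"
        )
    first = _unit_area(psd(trace.samples[:seg_len], trace.fs))
    last = _unit_area(psd(trace.samples[-seg_len:], trace.fs))
    delta = _fraction_below(last, split_hz) - _fraction_below(first, split_hz)
    return first, last, delta
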