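"""Synthetic surface-EMG generator with a programmed median-frequency drift.

Real cyclical-contraction sEMG shows a roughly linear downward drift of the
median frequency (MF) of its high-frequency content as the muscle fatigues.
This module emulates that statistical structure — amplitude-modulated,
band-limited Gaussian noise whose spectral center follows a known linear
trajectory — so every downstream stage (filtering, decomposition, MF
tracking, fatigue staging) can be tested against ground truth without
subject recordings.

The spectral drift is realised block-wise: white noise is band-pass
filtered in short 0.5 s blocks whose center frequency tracks the programmed
MF, and the blocks are crossfaded with 50%-overlap Hann windows (which sum
to unity). Drift rates of interest are slow (< 0.2 Hz/s), so the piecewise
approximation is far below the per-window MF estimation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import signal

from .errors import ParameterError
from .trace import SignalTrace

#: contraction fraction of each cycle; the remaining 25% is rest
_ACTIVE_FRACTION = 0.75
#: block length for the piecewise band-pass shaping, seconds
_BLOCK_S = 0.5


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic recording session.

    Defaults mirror a heavy-load cyclical elbow-flexion session: 2 kHz
    sampling, 4 s contraction cycles, and a linear MF drift from 136 Hz
    down to 122 Hz over 160 s (slope −0.0875 Hz/s).
    """

    duration_s: float = 160.0
    fs: float = 2000.0
    mf_start: float = 136.0
    mf_end: float = 122.0
    bandwidth: float = 40.0
    cycle_s: float = 4.0
    mod_depth: float = 0.5
    powerline_amp: float = 0.0
    noise_floor: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ParameterError(f"duration_s must be > 0, got {self.duration_s}")
        if not self.fs > 0:
            raise ParameterError(f"fs must be > 0, got {self.fs}")
        if not self.cycle_s > 0:
            raise ParameterError(f"cycle_s must be > 0, got {self.cycle_s}")
        if not (0 < self.mf_end <= self.mf_start):
            raise ParameterError(
                f"need 0 < mf_end <= mf_start, got mf_end={self.mf_end}, "
                f"mf_start={self.mf_start}"
            )
        if not self.mf_start < self.fs / 2:
            raise ParameterError(
                f"mf_start must be below Nyquist ({self.fs / 2} Hz), got {self.mf_start}"
            )
        if not self.bandwidth > 0:
            raise ParameterError(f"bandwidth must be > 0, got {self.bandwidth}")
        if not 0 <= self.mod_depth <= 1:
            raise ParameterError(f"mod_depth must be in [0, 1], got {self.mod_depth}")
        if self.powerline_amp < 0:
            raise ParameterError(f"powerline_amp must be >= 0, got {self.powerline_amp}")
        if self.noise_floor < 0:
            raise ParameterError(f"noise_floor must be >= 0, got {self.noise_floor}")


@dataclass(frozen=True)
class SynthResult:
    """Generated trace plus the ground truth it was built from."""

    trace: SignalTrace
    true_mf: Callable[[np.ndarray], np.ndarray]
    true_slope: float
    true_intercept: float
    spec: SynthSpec = field(repr=False)


def _burst_envelope(t: np.ndarray, cycle_s: float, mod_depth: float) -> np.ndarray:
    """Raised-cosine on–off contraction envelope, 1 at rest, up to 1+mod_depth."""
    phase = (t % cycle_s) / cycle_s
    active = phase < _ACTIVE_FRACTION
    burst = np.zeros_like(t)
    burst[active] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase[active] / _ACTIVE_FRACTION))
    return 1.0 + mod_depth * burst


def _shaped_noise(white: np.ndarray, fs: float, mf_of_t: Callable, bandwidth: float) -> np.ndarray:
    """Band-pass shape `white` block-wise so its center tracks mf_of_t."""
    n = white.size
    block = max(int(round(_BLOCK_S * fs)), 32)
    hop = block // 2
    win = signal.windows.hann(block, sym=False)
    ctx = block  # extra context per side so filter transients stay outside the block
    out = np.zeros(n)
    cov = np.zeros(n)
    nyq = fs / 2.0
    for start in range(0, n, hop):
        stop = min(start + block, n)
        if stop - start < 8:
            break
        t_center = (start + (stop - start) / 2.0) / fs
        fc = float(mf_of_t(np.asarray(t_center)))
        lo = max(fc - bandwidth / 2.0, 1.0)
        hi = min(fc + bandwidth / 2.0, 0.98 * nyq)
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        a, b = max(0, start - ctx), min(n, stop + ctx)
        filt = signal.sosfiltfilt(sos, white[a:b])
        seg = filt[start - a : stop - a]
        w = win[: stop - start]
        out[start:stop] += seg * w
        cov[start:stop] += w
    return out / np.maximum(cov, 1e-12)


def generate(spec: SynthSpec) -> SynthResult:
    """Generate one synthetic sEMG session.

    The trace is Gaussian noise band-pass shaped around a linearly drifting
    center frequency, multiplied by a cyclic contraction envelope, with
    optional 50 Hz powerline interference and a broadband noise floor. A
    fixed seed yields a bit-identical trace; the single RNG stream is
    consumed in fixed order (shaping noise, floor noise, powerline phase)
    so seeds are portable across parameter choices.
    """
    n = int(round(spec.duration_s * spec.fs))
    slope = (spec.mf_end - spec.mf_start) / spec.duration_s
    intercept = spec.mf_start

    def true_mf(t):
        t = np.asarray(t, dtype=float)
        return intercept + slope * np.clip(t, 0.0, spec.duration_s)

    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(n)
    floor = rng.standard_normal(n)
    powerline_phase = rng.uniform(0.0, 2.0 * np.pi)

    band = _shaped_noise(white, spec.fs, true_mf, spec.bandwidth)
    band /= np.sqrt(np.mean(band**2))  # unit-RMS muscle component

    t = np.arange(n) / spec.fs
    x = band * _burst_envelope(t, spec.cycle_s, spec.mod_depth)
    if spec.noise_floor > 0:
        x = x + np.sqrt(spec.noise_floor) * floor
    if spec.powerline_amp > 0:
        x = x + spec.powerline_amp * np.sin(2.0 * np.pi * 50.0 * t + powerline_phase)

    trace = SignalTrace(x, spec.fs)
    return SynthResult(
        trace=trace,
        true_mf=true_mf,
        true_slope=slope,
        true_intercept=intercept,
        spec=spec,
    )
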