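"""Uniformly sampled signal container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled voltage series.

    Parameters
    ----------
    samples : array-like
        Voltage samples (volts). Stored as a read-only float64 array.
    fs : float
        Sampling rate in Hz; must be positive.
    t0 : float
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=np.float64)
        if x.ndim != 1:
            raise InputError(f"samples must be one-dimensional, got shape {x.shape}")
        if x.size < 2:
            raise InputError(f"trace needs at least 2 samples, got {x.size}")
        if not np.all(np.isfinite(x)):
            bad = int(np.flatnonzero(~np.isfinite(x))[0])
            raise InputError(f"non-finite sample at index {bad}")
        if not (self.fs > 0):
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        x = x.copy()
        x.setflags(write=False)
        object.__setattr__(self, "samples", x)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "SignalTrace":
        """Return a trace with the same timing but new samples."""
        return SignalTrace(samples, self.fs, self.t0)
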