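"""Signal conditioning: band-pass (10–400 Hz) plus 50 Hz notch, zero-phase.

The filter family and order are community-standard choices for sEMG
conditioning: a 4th-order Butterworth band-pass and a second-order IIR
notch (Q = 30), both applied forward–backward so no group delay shifts the
analysis windows in time.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import InputTooShortError, ParameterError
from .trace import SignalTrace

BUTTER_ORDER = 4
DEFAULT_NOTCH_Q = 30.0


def _bandpass_sos(band_low: float, band_high: float, fs: float) -> np.ndarray:
    return signal.butter(
        BUTTER_ORDER, [band_low, band_high], btype="bandpass", fs=fs, output="sos"
    )


def _notch_ba(notch: float, q: float, fs: float):
    return signal.iirnotch(notch, q, fs=fs)


def condition(
    trace: SignalTrace,
    band_low: float = 10.0,
    band_high: float = 400.0,
    notch: float = 50.0,
    notch_q: float = DEFAULT_NOTCH_Q,
) -> SignalTrace:
    """Band-pass and notch-filter a trace, zero-phase.

    Parameters
    ----------
    trace : SignalTrace
        Input signal.
    band_low, band_high : float
        Pass-band edges in Hz; must satisfy 0 < band_low < band_high < fs/2.
    notch : float
        Powerline frequency to suppress (Hz), 0 < notch < fs/2.
    notch_q : float
        Notch quality factor (center / −3 dB width).

    Returns
    -------
    SignalTrace
        Same length, rate and start time; out-of-band and powerline
        content attenuated with no group delay.
    """
    fs = trace.fs
    nyq = fs / 2.0
    if not (0 < band_low < band_high):
        raise ParameterError(
            f"need 0 < band_low < band_high, got {band_low}, {band_high}"
        )
    if band_high >= nyq:
        raise ParameterError(f"band_high={band_high} Hz must be below Nyquist ({nyq} Hz)")
    if not (0 < notch < nyq):
        raise ParameterError(f"notch={notch} Hz must lie in (0, Nyquist={nyq} Hz)")

    # forward-backward doubles the effective order; warm-up padding is
    # odd-symmetric over 3x the (doubled) filter order
    padlen = 3 * 2 * BUTTER_ORDER * 2
    if trace.n <= padlen:
        raise InputTooShortError(
            f"trace of {trace.n} samples is shorter than the filter warm-up "
            f"({padlen + 1} samples)"
        )

    sos = _bandpass_sos(band_low, band_high, fs)
    y = signal.sosfiltfilt(sos, trace.samples, padtype="odd", padlen=padlen)
    b, a = _notch_ba(notch, notch_q, fs)
    y = signal.filtfilt(b, a, y, padtype="odd", padlen=padlen)
    return trace.with_samples(y)


def bandpass_response(
    freqs_hz: np.ndarray,
    fs: float,
    band_low: float = 10.0,
    band_high: float = 400.0,
) -> np.ndarray:
    """Zero-phase band-pass magnitude response at the given frequencies.

    Forward–backward application squares the single-pass magnitude.
    """
    sos = _bandpass_sos(band_low, band_high, fs)
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(freqs_hz), fs=fs)
    return np.abs(h) ** 2


def notch_response(
    freqs_hz: np.ndarray, fs: float, notch: float = 50.0, q: float = DEFAULT_NOTCH_Q
) -> np.ndarray:
    """Zero-phase notch magnitude response at the given frequencies."""
    b, a = _notch_ba(notch, q, fs)
    _, h = signal.freqz(b, a, worN=np.atleast_1d(freqs_hz), fs=fs)
    return np.abs(h) ** 2
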