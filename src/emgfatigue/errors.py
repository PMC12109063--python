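"""Exception hierarchy for the fatigue pipeline."""


class EMGFatigueError(Exception):
    """Base class for all package errors."""


class ParameterError(EMGFatigueError, ValueError):
    """A parameter violates a stated bound (message names the bound)."""


class InputError(EMGFatigueError, ValueError):
    """Input data is malformed (non-finite samples, bad columns, ...)."""


class InputTooShortError(InputError):
    """Input trace is too short for the requested operation."""


class InsufficientDataError(InputError):
    """Too few observations for a statistical fit."""


class DegenerateSpectrumError(EMGFatigueError):
    """Spectrum carries no power; median frequency is undefined."""


class NoFatigueRangeError(EMGFatigueError):
    """Calibrated MF range is empty or inverted; estimator refuses it."""
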