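import numpy as np
import pytest

import emgfatigue as ef


@pytest.fixture(scope="session")
def fs() -> float:
    return 2000.0


@pytest.fixture(scope="session")
def drifting_session() -> ef.SynthResult:
    """One full-length synthetic session with the standard 136→122 Hz drift."""
    return ef.generate(ef.SynthSpec(seed=7))


@pytest.fixture(scope="session")
def stationary_trace(fs) -> ef.SignalTrace:
    """10 s of band-limited noise with a fixed 120 Hz spectral center."""
    spec = ef.SynthSpec(
        duration_s=10.0, mf_start=120.0, mf_end=120.0, bandwidth=40.0,
        powerline_amp=0.0, seed=11,
    )
    return ef.generate(spec).trace
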