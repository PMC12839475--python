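import numpy as np
import pytest

from tremorkit import AnalysisConfig, MagnitudeSignal, ScenarioSpec


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def scenario() -> ScenarioSpec:
    return ScenarioSpec()


def make_tone(
    freq_hz: float,
    amplitude: float = 1.0,
    offset: float = 0.0,
    duration_s: float = 10.0,
    fs: float = 200.0,
    filtered: bool = False,
    phase: float = 0.0,
) -> MagnitudeSignal:
    """A sinusoidal magnitude signal for spectral oracle tests."""
    t = np.arange(int(round(duration_s * fs))) / fs
    m = offset + amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
    return MagnitudeSignal(t=t, m=m, sampling_rate_hz=fs, filtered=filtered)
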