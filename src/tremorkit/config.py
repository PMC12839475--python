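"""Analysis configuration.

All tunable parameters of the tremor pipeline live in one immutable object so
that every report can embed the exact configuration that produced it.  The
defaults encode the standard analysis for high-frequency orthostatic tremor:
a 10-22 Hz fourth-order Butterworth band-pass around the 13-18 Hz tremor
band, peak search in the same band, and a 0.6 Hz dominance window around the
detected peak.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Mapping

import yaml

from .exceptions import ConfigError

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the tremor quantification pipeline.

    Parameters
    ----------
    sampling_rate_hz
        Nominal accelerometer sampling rate.  Recordings whose inferred rate
        deviates by more than 1% trigger a warning and this value is used.
    filter_order
        Design order passed to the Butterworth band-pass transform (an order
        of 4 yields an 8-pole band-pass, applied forward-backward).
    band_low_hz, band_high_hz
        Band-pass cutoff frequencies in Hz.
    peak_search_low_hz, peak_search_high_hz
        Frequency band searched for the tremor peak.
    dominance_window_hz
        Full width of the spectral window, centred on the peak, whose power
        is summed in the tremor-dominance numerator.
    dominance_cutoff
        Dominance value at or above which a tremor is called present.
    stability_tolerance_hz
        Maximum deviation from the standing tremor frequency for a
        supra-threshold load step to count as frequency-stable.
    """

    sampling_rate_hz: float = 200.0
    filter_order: int = 4
    band_low_hz: float = 10.0
    band_high_hz: float = 22.0
    peak_search_low_hz: float = 10.0
    peak_search_high_hz: float = 22.0
    dominance_window_hz: float = 0.6
    dominance_cutoff: float = 0.5
    stability_tolerance_hz: float = 0.5

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        if self.filter_order < 1 or int(self.filter_order) != self.filter_order:
            raise ConfigError("filter_order must be a positive integer")
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ConfigError("need 0 < band_low_hz < band_high_hz")
        if self.band_high_hz >= self.sampling_rate_hz / 2:
            raise ConfigError(
                f"band_high_hz={self.band_high_hz} must lie below the Nyquist "
                f"frequency {self.sampling_rate_hz / 2}"
            )
        if not (
            self.band_low_hz
            <= self.peak_search_low_hz
            < self.peak_search_high_hz
            <= self.band_high_hz
        ):
            raise ConfigError("peak search band must be contained in the filter passband")
        if self.dominance_window_hz <= 0:
            raise ConfigError("dominance_window_hz must be positive")
        if self.dominance_window_hz >= self.peak_search_high_hz - self.peak_search_low_hz:
            raise ConfigError("dominance_window_hz must be narrower than the search band")
        if not (0 < self.dominance_cutoff < 1):
            raise ConfigError("dominance_cutoff must lie in (0, 1)")
        if self.stability_tolerance_hz <= 0:
            raise ConfigError("stability_tolerance_hz must be positive")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: expected a YAML mapping")
        return cls.from_dict(d)
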