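"""Core domain containers.

The raw unit of measurement is one labelled triaxial recording
(:class:`AccelRecording`); the pipeline maps it to a scalar magnitude signal,
a one-sided power spectrum, and finally a :class:`TremorPeakResult`.  A
subject's leg-press session is a :class:`LoadSeriesResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import DataError

__all__ = [
    "CONDITIONS",
    "RecordingLabel",
    "AccelRecording",
    "MagnitudeSignal",
    "PowerSpectrum",
    "TremorPeakResult",
    "LoadStep",
    "LoadSeriesResult",
]

#: Measurement conditions of the study protocol: four body positions plus the
#: loaded leg-press condition.
CONDITIONS = (
    "supine_rest",
    "supine_leg_lifted",
    "seated_extended",
    "standing",
    "leg_press",
)


@dataclass(frozen=True)
class RecordingLabel:
    """Identifies what one recording measured.

    ``load_kg`` is required exactly when ``condition == "leg_press"`` and must
    be absent otherwise.
    """

    subject_id: str
    condition: str
    load_kg: Optional[float] = None
    side: str = "left"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise DataError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.side not in ("left", "right"):
            raise DataError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.condition == "leg_press":
            if self.load_kg is None:
                raise DataError("leg_press recordings require load_kg")
            if self.load_kg < 0:
                raise DataError("load_kg must be non-negative")
        elif self.load_kg is not None:
            raise DataError(f"load_kg is only meaningful for leg_press, not {self.condition}")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "condition": self.condition,
            "load_kg": self.load_kg,
            "side": self.side,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingLabel":
        return cls(
            subject_id=str(d["subject_id"]),
            condition=d["condition"],
            load_kg=d.get("load_kg"),
            side=d.get("side", "left"),
        )


@dataclass
class AccelRecording:
    """One triaxial accelerometer recording.

    ``t`` holds time stamps in seconds and ``x``, ``y``, ``z`` acceleration in
    m/s² along the device's orthogonal axes; all four arrays share length
    N >= 2 and the time stamps are strictly increasing and approximately
    uniform.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sampling_rate_hz: float
    label: Optional[RecordingLabel] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = self.t.size
        if n < 2:
            raise DataError(f"recording needs at least 2 samples, got {n}")
        for name in ("x", "y", "z"):
            if getattr(self, name).size != n:
                raise DataError(f"axis {name!r} length differs from time axis")
        if not np.all(np.diff(self.t) > 0):
            raise DataError("time stamps must be strictly increasing")
        if self.sampling_rate_hz <= 0:
            raise DataError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class MagnitudeSignal:
    """Scalar acceleration-magnitude series, optionally band-pass filtered.

    An unfiltered magnitude is a Euclidean norm and therefore non-negative;
    the filtered signal is zero-mean and signed.
    """

    t: np.ndarray
    m: np.ndarray
    sampling_rate_hz: float
    filtered: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if self.t.size != self.m.size:
            raise DataError("time and magnitude series differ in length")
        if not self.filtered and np.any(self.m < 0):
            raise DataError("unfiltered magnitude must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.m.size


@dataclass
class PowerSpectrum:
    """One-sided power spectrum on the FFT frequency grid 0 .. fs/2."""

    freqs_hz: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs_hz.size != self.power.size:
            raise DataError("frequency and power arrays differ in length")
        if self.freqs_hz.size and (
            self.freqs_hz[0] < 0 or np.any(np.diff(self.freqs_hz) <= 0)
        ):
            raise DataError("frequencies must be non-negative and ascending")
        if np.any(self.power < 0):
            raise DataError("power values must be non-negative")

    @property
    def resolution_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    def total_power(self, include_dc: bool = False) -> float:
        """Summed one-sided power; the DC bin is excluded by default."""
        return float(self.power.sum() if include_dc else self.power[1:].sum())


@dataclass(frozen=True)
class TremorPeakResult:
    """Spectral tremor characterization of one recording.

    ``dominance`` is the fraction of total (non-DC) spectral power within the
    configured window around the peak: close to one for a clear tremor, close
    to zero for noise.  ``tremor_present`` is the dominance-cutoff call.
    """

    peak_frequency_hz: float
    peak_height: float
    dominance: float
    tremor_present: bool
    label: Optional[RecordingLabel] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.dominance <= 1.0):
            raise DataError(f"dominance {self.dominance} outside [0, 1]")
        if self.peak_height < 0:
            raise DataError("peak_height must be non-negative")

    def to_dict(self) -> dict:
        return {
            "label": self.label.to_dict() if self.label else None,
            "peak_frequency_hz": self.peak_frequency_hz,
            "peak_height": self.peak_height,
            "dominance": self.dominance,
            "tremor_present": self.tremor_present,
        }


@dataclass(frozen=True)
class LoadStep:
    """One leg-press load step and its analysed recording."""

    load_kg: float
    result: TremorPeakResult

    def __post_init__(self) -> None:
        if self.load_kg <= 0:
            raise DataError("load_kg must be positive")


@dataclass
class LoadSeriesResult:
    """Load-response characterization of one subject's leg-press session.

    ``threshold_kg`` is the smallest load at and beyond which the tremor is
    consistently present (None when never sustained).  ``stable_frequency``
    says whether every supra-threshold peak stayed within the stability
    tolerance of the standing tremor frequency; ``amplitude_trend_rho`` is
    the Spearman correlation of peak height with load above threshold.
    """

    subject_id: str
    steps: Sequence[LoadStep] = field(default_factory=list)
    threshold_kg: Optional[float] = None
    standing_frequency_hz: Optional[float] = None
    stable_frequency: Optional[bool] = None
    amplitude_trend_rho: Optional[float] = None

    def __post_init__(self) -> None:
        loads = [s.load_kg for s in self.steps]
        if any(b <= a for a, b in zip(loads, loads[1:])):
            raise DataError("load steps must be strictly ascending in load")
        if self.threshold_kg is not None and self.threshold_kg not in loads:
            raise DataError("threshold_kg must equal the load of one of the steps")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "steps": [
                {"load_kg": s.load_kg, **s.result.to_dict()} for s in self.steps
            ],
            "threshold_kg": self.threshold_kg,
            "standing_frequency_hz": self.standing_frequency_hz,
            "stable_frequency": self.stable_frequency,
            "amplitude_trend_rho": self.amplitude_trend_rho,
        }
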