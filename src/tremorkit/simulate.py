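"""Seeded synthetic triaxial accelerometer recordings.

No raw patient recordings are available for this kind of study protocol, so
the generator provides ground-truth-labelled surrogates with the statistical
structure the analysis pipeline assumes:

* a constant gravity offset (9.81 m/s²) oriented per body position and
  tilted by a small random sensor-mounting rotation;
* a 1/f (pink) accelerometer noise floor plus white sensor noise, per axis;
* when the condition elicits tremor, a sinusoid at the subject's stable
  tremor frequency (13-18 Hz) with random phase and a random spatial
  direction, whose amplitude follows the subject's load-response law:
  zero below the subject's load threshold, then
  ``amplitude_at_threshold + amplitude_gain_per_kg * (load - threshold)``,
  i.e. piecewise-linear growth above a hard threshold.

The tremor direction is drawn uniformly on the sphere conditioned on having
at least a 0.6 projection onto the gravity axis: the sensor sits on the
proximal fibula with its long axis roughly along the tibia, and the leg's
extension tremor oscillates mainly along that axis.  This keeps the
magnitude transform (which to first order projects perturbations onto the
gravity direction) from annihilating the tremor, mirroring why the magnitude
analysis works on real recordings.

Everything is deterministic given seeds; per-recording seeds are derived
from series/cohort seeds via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .exceptions import DataError
from .types import AccelRecording, RecordingLabel

__all__ = [
    "SubjectProfile",
    "ScenarioSpec",
    "CohortMember",
    "one_over_f_noise",
    "simulate_recording",
    "simulate_load_series",
    "simulate_cohort",
    "preset_profiles",
]

# ---------------------------------------------------------------------------
# Generator defaults (all amplitudes in m/s²).  Calibrated so that at the
# subject's load threshold the in-band tremor-to-noise ratio exceeds 10 dB
# and the dominance statistic clears the 0.5 presence cutoff with margin.
GRAVITY_M_S2 = 9.81
DEFAULT_WHITE_NOISE_SD = 0.03
DEFAULT_NOISE_FLOOR = 0.05
DEFAULT_AMPLITUDE_AT_THRESHOLD = 0.2
DEFAULT_AMPLITUDE_GAIN_PER_KG = 0.008
DEFAULT_STANDING_AMPLITUDE = 0.3
#: Minimum |cos| between tremor direction and gravity axis (sensor placement).
MIN_GRAVITY_PROJECTION = 0.6
#: SD of the random sensor-mounting tilt, radians (~3 degrees).
TILT_SD_RAD = 0.05
#: Relative SD of trial-to-trial tremor amplitude variability.
DEFAULT_AMPLITUDE_JITTER = 0.1

#: Gravity direction in device coordinates per condition.  Upright or seated
#: postures put gravity along the device long axis (z); supine postures along
#: a transverse axis (y).  Irrelevant to the band-passed analysis, but keeps
#: the raw signals physically plausible.
_GRAVITY_AXIS = {
    "standing": np.array([0.0, 0.0, 1.0]),
    "seated_extended": np.array([0.0, 0.0, 1.0]),
    "leg_press": np.array([0.0, 0.0, 1.0]),
    "supine_rest": np.array([0.0, 1.0, 0.0]),
    "supine_leg_lifted": np.array([0.0, 1.0, 0.0]),
}

_DEFAULT_SCHEDULE = tuple(float(k) for k in range(10, 101, 10))


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth generative parameters for one synthetic subject.

    ``threshold_kg`` absent marks a non-responder: no leg-press load elicits
    tremor.  ``seated_tremor`` marks the phenotype in which a tremor of
    standing amplitude already appears when seated with the knee extended.
    """

    subject_id: str
    tremor_frequency_hz: float
    threshold_kg: Optional[float] = None
    amplitude_at_threshold: float = DEFAULT_AMPLITUDE_AT_THRESHOLD
    amplitude_gain_per_kg: float = DEFAULT_AMPLITUDE_GAIN_PER_KG
    standing_amplitude: float = DEFAULT_STANDING_AMPLITUDE
    noise_floor: float = DEFAULT_NOISE_FLOOR
    white_noise_sd: float = DEFAULT_WHITE_NOISE_SD
    seated_tremor: bool = False
    amplitude_jitter: float = DEFAULT_AMPLITUDE_JITTER
    #: Optional override for the amplitude-load law: callable(load, profile)
    #: returning the tremor amplitude at that load.
    load_law: Optional[Callable[[float, "SubjectProfile"], float]] = None

    def __post_init__(self) -> None:
        if not (13.0 <= self.tremor_frequency_hz <= 18.0):
            raise DataError("tremor_frequency_hz must lie in the 13-18 Hz POT band")
        if self.threshold_kg is not None and self.threshold_kg <= 0:
            raise DataError("threshold_kg must be positive when present")
        if self.amplitude_at_threshold <= 0:
            raise DataError("amplitude_at_threshold must be positive")
        if self.amplitude_gain_per_kg < 0:
            raise DataError("amplitude_gain_per_kg must be non-negative")
        if self.standing_amplitude <= 0:
            raise DataError("standing_amplitude must be positive")
        if self.noise_floor <= 0:
            raise DataError("noise_floor must be positive")
        if self.white_noise_sd < 0:
            raise DataError("white_noise_sd must be non-negative")

    def tremor_amplitude(self, condition: str, load_kg: Optional[float]) -> float:
        """Ground-truth tremor amplitude for a condition/load (m/s²)."""
        if condition == "standing":
            return self.standing_amplitude
        if condition == "seated_extended":
            return self.standing_amplitude if self.seated_tremor else 0.0
        if condition == "leg_press":
            if self.threshold_kg is None or load_kg is None or load_kg < self.threshold_kg:
                return 0.0
            if self.load_law is not None:
                return self.load_law(load_kg, self)
            return self.amplitude_at_threshold + self.amplitude_gain_per_kg * (
                load_kg - self.threshold_kg
            )
        return 0.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Recording/session geometry: duration, rate, load schedule, conditions."""

    duration_s: float = 10.0
    sampling_rate_hz: float = 200.0
    load_schedule_kg: Sequence[float] = _DEFAULT_SCHEDULE
    conditions: Sequence[str] = (
        "supine_rest",
        "supine_leg_lifted",
        "seated_extended",
        "standing",
    )

    def __post_init__(self) -> None:
        n = self.duration_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise DataError("duration_s * sampling_rate_hz must be an integer >= 2")
        loads = list(self.load_schedule_kg)
        if any(b <= a for a, b in zip(loads, loads[1:])) or any(l <= 0 for l in loads):
            raise DataError("load schedule must be ascending and positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


def one_over_f_noise(
    n_samples: int,
    sampling_rate_hz: float,
    scale: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Zero-mean pink noise with expected PSD proportional to 1/f.

    White Gaussian noise is shaped in the frequency domain by 1/sqrt(f)
    (power goes as 1/f), the DC bin is zeroed, and the series is rescaled so
    its standard deviation equals ``scale``.
    """
    if n_samples < 16:
        raise DataError("need at least 16 samples for 1/f shaping")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate_hz)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    series = np.fft.irfft(spec * shape, n=n_samples)
    series -= series.mean()
    sd = series.std()
    if scale == 0.0 or sd == 0.0:
        return np.zeros(n_samples)
    return series * (scale / sd)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _small_rotation(rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix for a small random mounting tilt (Rodrigues form)."""
    axis = _unit(rng.standard_normal(3))
    angle = rng.normal(0.0, TILT_SD_RAD)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _tremor_direction(rng: np.random.Generator, g_hat: np.ndarray) -> np.ndarray:
    """Random unit vector with |cos| to the gravity axis >= the placement
    minimum (rejection sampling; deterministic under the generator)."""
    while True:
        d = _unit(rng.standard_normal(3))
        if abs(d @ g_hat) >= MIN_GRAVITY_PROJECTION:
            return d


def simulate_recording(
    profile: SubjectProfile,
    label: RecordingLabel,
    spec: ScenarioSpec,
    seed: int | np.random.Generator,
) -> AccelRecording:
    """One 10 s triaxial recording: gravity + pink/white noise + tremor.

    Bit-identical output for identical inputs and seed.  The tremor sinusoid
    is present only when the profile's load-response law says so for this
    condition/load; its per-trial amplitude carries a small multiplicative
    log-normal jitter (``profile.amplitude_jitter``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_samples
    fs = spec.sampling_rate_hz
    t = np.arange(n) / fs

    g_hat = _unit(_small_rotation(rng) @ _GRAVITY_AXIS[label.condition])
    gravity = GRAVITY_M_S2 * g_hat

    axes = np.empty((3, n))
    for i in range(3):
        axes[i] = one_over_f_noise(n, fs, profile.noise_floor, rng)
        if profile.white_noise_sd > 0:
            axes[i] += rng.normal(0.0, profile.white_noise_sd, size=n)

    amplitude = profile.tremor_amplitude(label.condition, label.load_kg)
    if amplitude > 0.0:
        if profile.amplitude_jitter > 0:
            amplitude *= np.exp(rng.normal(0.0, profile.amplitude_jitter))
        direction = _tremor_direction(rng, g_hat)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        tremor = amplitude * np.sin(2.0 * np.pi * profile.tremor_frequency_hz * t + phase)
        axes += direction[:, None] * tremor[None, :]

    axes += gravity[:, None]
    return AccelRecording(
        t=t, x=axes[0], y=axes[1], z=axes[2], sampling_rate_hz=fs, label=label
    )


def _child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_load_series(
    profile: SubjectProfile,
    spec: ScenarioSpec,
    seed: int,
    include_standing: bool = False,
) -> list[AccelRecording]:
    """One recording per scheduled leg-press load, ascending; optionally a
    standing recording first.  Per-recording seeds derive from ``seed``."""
    loads = list(spec.load_schedule_kg)
    rngs = _child_seeds(seed, len(loads) + 1)
    out: list[AccelRecording] = []
    if include_standing:
        out.append(
            simulate_recording(
                profile,
                RecordingLabel(subject_id=profile.subject_id, condition="standing"),
                spec,
                rngs[0],
            )
        )
    for load, rng in zip(loads, rngs[1:]):
        out.append(
            simulate_recording(
                profile,
                RecordingLabel(
                    subject_id=profile.subject_id, condition="leg_press", load_kg=load
                ),
                spec,
                rng,
            )
        )
    return out


@dataclass
class CohortMember:
    """One synthetic subject: ground-truth profile plus generated session."""

    profile: SubjectProfile
    position_recordings: list[AccelRecording] = field(default_factory=list)
    load_recordings: list[AccelRecording] = field(default_factory=list)


def preset_profiles() -> list[SubjectProfile]:
    """Seven-subject preset mirroring the reference cohort's phenotype mix:
    five plain threshold-responders, one non-responder (s5) and one
    seated-tremor responder (s7); frequencies span the observed 14.24-16.00
    Hz range."""
    freqs = [14.31, 14.89, 15.31, 16.00, 15.41, 14.40, 14.24]
    thresholds: list[Optional[float]] = [30.0, 40.0, 20.0, 50.0, None, 60.0, 40.0]
    profiles = []
    for i, (f, thr) in enumerate(zip(freqs, thresholds), start=1):
        profiles.append(
            SubjectProfile(
                subject_id=f"s{i}",
                tremor_frequency_hz=f,
                threshold_kg=thr,
                seated_tremor=(i == 7),
            )
        )
    return profiles


def _sample_profile(subject_id: str, rng: np.random.Generator) -> SubjectProfile:
    """Random profile from documented ranges: frequency uniform over the
    observed 14.24-16.00 Hz span; 1-in-7 non-responders; thresholds on the
    10 kg grid between 20 and 70 kg; 1-in-7 seated-tremor phenotype."""
    freq = rng.uniform(14.24, 16.00)
    responder = rng.random() < 6.0 / 7.0
    threshold = float(rng.choice(np.arange(20.0, 80.0, 10.0))) if responder else None
    seated = responder and rng.random() < 1.0 / 6.0
    return SubjectProfile(
        subject_id=subject_id,
        tremor_frequency_hz=float(freq),
        threshold_kg=threshold,
        seated_tremor=seated,
    )


def simulate_cohort(
    n_subjects: int,
    seed: int,
    spec: ScenarioSpec | None = None,
    preset: bool = False,
    generate: bool = True,
) -> list[CohortMember]:
    """Sample subject profiles and (optionally) their full sessions.

    With ``preset=True`` (requires ``n_subjects == 7``) the fixed phenotype
    mix of :func:`preset_profiles` is used instead of random sampling; the
    recordings themselves are still seeded from ``seed``.
    """
    if n_subjects < 1:
        raise DataError("n_subjects must be >= 1")
    spec = spec or ScenarioSpec()
    if preset:
        if n_subjects != 7:
            raise DataError("the preset cohort has exactly 7 subjects")
        profiles = preset_profiles()
    else:
        rngs = _child_seeds(seed, n_subjects)
        profiles = [_sample_profile(f"s{i + 1}", rngs[i]) for i in range(n_subjects)]

    members = []
    session_seeds = np.random.SeedSequence(seed).spawn(2 * n_subjects)
    for i, profile in enumerate(profiles):
        member = CohortMember(profile=profile)
        if generate:
            pos_rngs = np.random.default_rng(session_seeds[2 * i]).spawn(
                len(spec.conditions)
            )
            for cond, rng in zip(spec.conditions, pos_rngs):
                member.position_recordings.append(
                    simulate_recording(
                        profile,
                        RecordingLabel(subject_id=profile.subject_id, condition=cond),
                        spec,
                        rng,
                    )
                )
            series_seed = int(
                np.random.default_rng(session_seeds[2 * i + 1]).integers(2**31 - 1)
            )
            member.load_recordings = simulate_load_series(
                profile, spec, series_seed, include_standing=True
            )
        members.append(member)
    return members
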