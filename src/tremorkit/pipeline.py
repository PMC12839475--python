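"""Spectral tremor quantification for one triaxial recording.

The pipeline is: vector magnitude -> zero-phase Butterworth band-pass ->
one-sided FFT power spectrum -> in-band peak -> tremor dominance.  The
magnitude transform removes the dependence on sensor orientation; the
band-pass (default 10-22 Hz) isolates the 13-18 Hz orthostatic-tremor band
from the 1/f accelerometer noise floor below and sensor noise above; the
dominance statistic normalises the power near the peak by the total power of
the filtered signal, so a value near 1 means the spectrum is essentially a
single tremor line and a value near 0 means the peak is part of the noise.

Normalisation convention
------------------------
``compute_spectrum`` removes the sample mean, takes the length-N DFT and
reports a one-sided power spectrum ``P[k] = c_k |X_k|^2 / N`` with ``c_k = 2``
for interior bins and ``c_k = 1`` for the DC and (even N) Nyquist bins.  Under
this convention the non-DC one-sided power sums to ``N`` times the biased
sample variance of the signal (Parseval).  Peak heights are therefore in
(m/s²)² · N — arbitrary units, comparable across equal-length recordings.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig
from .exceptions import ConfigError, DataError
from .types import AccelRecording, MagnitudeSignal, PowerSpectrum, TremorPeakResult

__all__ = [
    "vector_magnitude",
    "bandpass",
    "bandpass_response",
    "compute_spectrum",
    "find_peak",
    "tremor_dominance",
    "analyze_recording",
]


def vector_magnitude(rec: AccelRecording) -> MagnitudeSignal:
    """Euclidean norm of the triaxial acceleration, sample by sample.

    m_i = sqrt(x_i² + y_i² + z_i²).  The result is invariant under any fixed
    rotation applied jointly to the three axes, so downstream analysis does
    not depend on how the sensor was oriented on the leg.
    """
    m = np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)
    return MagnitudeSignal(
        t=rec.t, m=m, sampling_rate_hz=rec.sampling_rate_hz, filtered=False
    )


def _design_sos(cfg: AnalysisConfig, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if cfg.band_high_hz >= nyq:
        raise ConfigError(
            f"band_high_hz={cfg.band_high_hz} Hz is not below Nyquist ({nyq} Hz)"
        )
    return sps.butter(
        cfg.filter_order,
        [cfg.band_low_hz, cfg.band_high_hz],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def bandpass(sig: MagnitudeSignal, cfg: AnalysisConfig) -> MagnitudeSignal:
    """Zero-phase Butterworth band-pass of the magnitude signal.

    The filter is designed at ``cfg.filter_order`` (a band-pass of order 4
    has 8 poles) and applied forward-backward, squaring the magnitude
    response and cancelling the phase.  DC and the gravity offset are far
    outside the passband, so the output is zero-mean to numerical precision.
    """
    if sig.filtered:
        raise DataError("signal is already filtered")
    sos = _design_sos(cfg, sig.sampling_rate_hz)
    # sosfiltfilt pads with 3 * (2 * n_sections + 1) samples on each side
    min_len = 3 * (2 * sos.shape[0] + 1)
    if sig.n_samples <= min_len:
        raise DataError(
            f"signal too short for stable filtering: {sig.n_samples} samples, "
            f"need more than {min_len}"
        )
    m = sps.sosfiltfilt(sos, sig.m)
    return MagnitudeSignal(
        t=sig.t, m=m, sampling_rate_hz=sig.sampling_rate_hz, filtered=True
    )


def bandpass_response(freq_hz: float, cfg: AnalysisConfig, fs: float | None = None) -> float:
    """Squared-magnitude (forward-backward) response of the designed filter
    at one frequency — the analytic steady-state gain of :func:`bandpass`."""
    fs = cfg.sampling_rate_hz if fs is None else fs
    sos = _design_sos(cfg, fs)
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)


def compute_spectrum(sig: MagnitudeSignal) -> PowerSpectrum:
    """One-sided FFT power spectrum of the mean-removed filtered signal.

    See the module docstring for the normalisation; the full 10 s recording
    is transformed directly (rectangular window, no segment averaging) so the
    grid resolution is 1/duration = 0.1 Hz at the protocol's 10 s length.
    """
    if not sig.filtered:
        raise DataError("compute_spectrum expects the band-pass-filtered signal")
    n = sig.n_samples
    m = sig.m - sig.m.mean()
    spec = np.fft.rfft(m)
    power = np.abs(spec) ** 2 / n
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not duplicated on the two-sided grid
    freqs = np.fft.rfftfreq(n, d=1.0 / sig.sampling_rate_hz)
    return PowerSpectrum(freqs_hz=freqs, power=power)


def find_peak(spec: PowerSpectrum, cfg: AnalysisConfig) -> tuple[float, float]:
    """Frequency and power of the strongest bin in the peak-search band.

    Ties break toward the lower frequency (``argmax`` returns the first
    maximum on the ascending grid).
    """
    mask = (spec.freqs_hz >= cfg.peak_search_low_hz) & (
        spec.freqs_hz <= cfg.peak_search_high_hz
    )
    if not mask.any():
        raise ConfigError(
            f"no spectral bins in search band "
            f"[{cfg.peak_search_low_hz}, {cfg.peak_search_high_hz}] Hz"
        )
    band_freqs = spec.freqs_hz[mask]
    band_power = spec.power[mask]
    k = int(np.argmax(band_power))
    return float(band_freqs[k]), float(band_power[k])


def tremor_dominance(
    spec: PowerSpectrum, peak_frequency_hz: float, cfg: AnalysisConfig
) -> float:
    """Fraction of total signal power within the window around the peak.

    Sums the one-sided power over bins with |f - f_peak| <= window/2
    (endpoints inclusive: 7 bins at 0.1 Hz resolution for the default 0.6 Hz
    window) and divides by the total non-DC power of the filtered signal.
    Degenerate all-zero spectra yield 0 with a warning.
    """
    if not (spec.freqs_hz[0] <= peak_frequency_hz <= spec.freqs_hz[-1]):
        raise DataError(f"peak frequency {peak_frequency_hz} Hz outside spectrum range")
    total = spec.total_power(include_dc=False)
    if total <= 0.0:
        warnings.warn("degenerate recording: zero total spectral power", stacklevel=2)
        return 0.0
    half = cfg.dominance_window_hz / 2.0
    # small tolerance so endpoint bins are robust to grid round-off
    win = np.abs(spec.freqs_hz - peak_frequency_hz) <= half * (1 + 1e-9)
    win[0] = False  # DC never contributes
    dom = float(spec.power[win].sum() / total)
    return min(dom, 1.0)


def analyze_recording(rec: AccelRecording, cfg: AnalysisConfig | None = None) -> TremorPeakResult:
    """Full pipeline for one recording: magnitude, band-pass, spectrum,
    in-band peak, dominance, and the presence call
    ``tremor_present = dominance >= cfg.dominance_cutoff``."""
    cfg = cfg or AnalysisConfig()
    filtered = bandpass(vector_magnitude(rec), cfg)
    spec = compute_spectrum(filtered)
    peak_freq, peak_height = find_peak(spec, cfg)
    dom = tremor_dominance(spec, peak_freq, cfg)
    return TremorPeakResult(
        peak_frequency_hz=peak_freq,
        peak_height=peak_height,
        dominance=dom,
        tremor_present=dom >= cfg.dominance_cutoff,
        label=rec.label,
    )
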