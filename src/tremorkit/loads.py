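"""Load-response characterization across an incremental leg-press session.

A subject holds an isometric leg extension against loads increasing in 10 kg
steps (10 kg up to at most 100 kg), with one 10 s recording per load.  This
module estimates, per subject:

* the load threshold — the smallest load at and beyond which the tremor is
  *consistently* present (dominance at or above the cutoff at that step and
  every later step; an isolated supra-cutoff excursion does not count);
* frequency stability — whether every supra-threshold peak frequency stays
  within a tolerance of the subject's standing tremor frequency;
* the amplitude trend — the Spearman rank correlation between load and
  spectral peak height over the supra-threshold steps.

It also provides a small-sample Spearman correlation with an exact
permutation p-value, used for cross-subject tests such as body weight versus
load threshold.
"""

from __future__ import annotations

import math
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .config import AnalysisConfig
from .exceptions import DataError
from .pipeline import analyze_recording
from .types import AccelRecording, LoadSeriesResult, LoadStep, TremorPeakResult

__all__ = [
    "detect_load_threshold",
    "frequency_stability",
    "amplitude_trend",
    "spearman_correlation",
    "analyze_load_series",
]


def _check_steps(steps: Sequence[LoadStep]) -> None:
    if not steps:
        raise DataError("empty load series")
    loads = [s.load_kg for s in steps]
    if any(b <= a for a, b in zip(loads, loads[1:])):
        raise DataError("load steps must be strictly ascending")


def detect_load_threshold(
    steps: Sequence[LoadStep], cfg: AnalysisConfig | None = None
) -> Optional[float]:
    """Smallest load from which tremor presence is sustained to the end.

    Returns the load of the earliest step j such that dominance >= cutoff at
    step j *and at every subsequent step*; ``None`` if no such step exists
    (non-responder, or presence never sustained).
    """
    cfg = cfg or AnalysisConfig()
    _check_steps(steps)
    threshold = None
    # scan from the top load down while presence holds
    for step in reversed(steps):
        if step.result.dominance >= cfg.dominance_cutoff:
            threshold = step.load_kg
        else:
            break
    return threshold


def _supra(steps: Sequence[LoadStep], threshold_kg: float) -> list[LoadStep]:
    return [s for s in steps if s.load_kg >= threshold_kg]


def frequency_stability(
    steps: Sequence[LoadStep],
    standing_frequency_hz: float,
    threshold_kg: float,
    cfg: AnalysisConfig | None = None,
) -> bool:
    """True iff every supra-threshold peak frequency lies within
    ``cfg.stability_tolerance_hz`` of the standing tremor frequency."""
    cfg = cfg or AnalysisConfig()
    _check_steps(steps)
    supra = _supra(steps, threshold_kg)
    if not supra:
        raise DataError("no steps at or above the stated threshold")
    return all(
        abs(s.result.peak_frequency_hz - standing_frequency_hz)
        <= cfg.stability_tolerance_hz
        for s in supra
    )


def amplitude_trend(
    steps: Sequence[LoadStep], threshold_kg: float
) -> Optional[float]:
    """Spearman rank correlation of peak height with load above threshold.

    Returns ``None`` (insufficient data, not an error) when fewer than three
    supra-threshold steps are available.
    """
    _check_steps(steps)
    supra = _supra(steps, threshold_kg)
    if len(supra) < 3:
        return None
    loads = [s.load_kg for s in supra]
    heights = [s.result.peak_height for s in supra]
    rho, _ = spearman_correlation(loads, heights, exact_p=False)
    return rho


def _rank_rho(ra: np.ndarray, rb: np.ndarray) -> float:
    """Product-moment correlation of two rank vectors (average ranks)."""
    da = ra - ra.mean()
    db = rb - rb.mean()
    denom = math.sqrt(float(da @ da) * float(db @ db))
    if denom == 0.0:
        return math.nan
    return float(da @ db) / denom


def spearman_correlation(
    a: Sequence[float], b: Sequence[float], exact_p: bool | None = None
) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    rho is the Pearson correlation of the average-rank vectors.  For
    n <= 8 (or when ``exact_p=True``) the p-value is exact: the fraction of
    all n! orderings of one variable whose |rho| is at least the observed
    |rho|.  Larger samples use the usual t approximation with n - 2 degrees
    of freedom.  A constant input yields ``(nan, nan)`` — rho is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise DataError("input vectors must have equal length")
    n = a.size
    if n < 3:
        raise DataError(f"need n >= 3, got {n}")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    rho = _rank_rho(ra, rb)
    if math.isnan(rho):
        return math.nan, math.nan
    if exact_p is None:
        exact_p = n <= 8
    if exact_p:
        observed = abs(rho) - 1e-12
        hits = sum(
            abs(_rank_rho(ra, np.asarray(perm))) >= observed
            for perm in permutations(rb)
        )
        p = hits / math.factorial(n)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, p


def analyze_load_series(
    recordings: Sequence[AccelRecording],
    cfg: AnalysisConfig | None = None,
    standing: AccelRecording | None = None,
) -> LoadSeriesResult:
    """Analyse one subject's leg-press session end to end.

    Each recording must be a ``leg_press`` recording with a load label; they
    are analysed individually, ordered by load, and summarised into threshold,
    frequency-stability and amplitude-trend statistics.  Stability requires a
    standing recording (for the reference frequency) and a detected threshold.
    """
    cfg = cfg or AnalysisConfig()
    if not recordings:
        raise DataError("no leg-press recordings supplied")
    steps = []
    subject_ids = set()
    for rec in recordings:
        if rec.label is None or rec.label.condition != "leg_press":
            raise DataError("load series requires leg_press-labelled recordings")
        subject_ids.add(rec.label.subject_id)
        steps.append(LoadStep(load_kg=rec.label.load_kg, result=analyze_recording(rec, cfg)))
    if len(subject_ids) != 1:
        raise DataError(f"recordings span multiple subjects: {sorted(subject_ids)}")
    steps.sort(key=lambda s: s.load_kg)

    standing_result: Optional[TremorPeakResult] = None
    if standing is not None:
        standing_result = analyze_recording(standing, cfg)

    threshold = detect_load_threshold(steps, cfg)
    stable = None
    trend = None
    if threshold is not None:
        if standing_result is not None:
            stable = frequency_stability(
                steps, standing_result.peak_frequency_hz, threshold, cfg
            )
        trend = amplitude_trend(steps, threshold)
    return LoadSeriesResult(
        subject_id=subject_ids.pop(),
        steps=steps,
        threshold_kg=threshold,
        standing_frequency_hz=(
            standing_result.peak_frequency_hz if standing_result else None
        ),
        stable_frequency=stable,
        amplitude_trend_rho=trend,
    )
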