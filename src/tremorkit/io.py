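"""Reading and writing recordings, reports and scenario directories.

On-disk contracts
-----------------
Recordings are plain CSV with header ``t,x,y,z`` — time in seconds,
acceleration in m/s².  The recording label travels in a JSON sidecar with
the same basename and a ``.meta.json`` suffix, so file names stay free-form
and a write/read round trip is exact.  Analysis reports are JSON and always
embed the full configuration that produced them, for auditability.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .exceptions import DataError, FormatError
from .types import AccelRecording, LoadSeriesResult, RecordingLabel, TremorPeakResult

__all__ = [
    "read_recording",
    "write_recording",
    "write_report",
    "read_report",
    "write_scenario",
]

logger = logging.getLogger("tremorkit")

_AXIS_COLUMNS = ("t", "x", "y", "z")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def read_recording(
    path: str | Path, config: AnalysisConfig | None = None
) -> AccelRecording:
    """Read one recording CSV (columns ``t,x,y,z``) plus its label sidecar.

    The sampling rate is inferred as the reciprocal median time step; when a
    configuration is supplied and the inferred rate deviates from the
    configured one by more than 1%, a warning is emitted and the configured
    rate is used.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: not a parseable CSV ({exc})") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _AXIS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    try:
        data = {c: df[c].to_numpy(dtype=float) for c in _AXIS_COLUMNS}
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric values ({exc})") from exc
    t = data["t"]
    if t.size < 2:
        raise DataError(f"{path}: fewer than 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError(f"{path}: time stamps are not strictly increasing")
    inferred_rate = 1.0 / float(np.median(dt))
    rate = inferred_rate
    if config is not None:
        if abs(inferred_rate - config.sampling_rate_hz) / config.sampling_rate_hz > 0.01:
            warnings.warn(
                f"{path}: inferred sampling rate {inferred_rate:.2f} Hz deviates "
                f">1% from configured {config.sampling_rate_hz:.2f} Hz; using the "
                "configured rate",
                stacklevel=2,
            )
        rate = config.sampling_rate_hz

    label = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            label = RecordingLabel.from_dict(json.load(fh))
    return AccelRecording(
        t=t, x=data["x"], y=data["y"], z=data["z"], sampling_rate_hz=rate, label=label
    )


def write_recording(rec: AccelRecording, path: str | Path) -> None:
    """Write a recording CSV (full ``repr`` float precision, so a re-read
    reproduces the samples exactly) and its label sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"t": rec.t, "x": rec.x, "y": rec.y, "z": rec.z})
    # %.17g guarantees binary64 round-trips exactly through the CSV
    df.to_csv(path, index=False, float_format="%.17g")
    if rec.label is not None:
        with open(_sidecar_path(path), "w") as fh:
            json.dump(rec.label.to_dict(), fh, indent=1)
    logger.debug("wrote recording %s (%d samples)", path, rec.n_samples)


ReportItem = Union[TremorPeakResult, LoadSeriesResult]


def write_report(
    results: Sequence[ReportItem],
    path: str | Path,
    config: AnalysisConfig | None = None,
) -> None:
    """Write analysis results to a JSON report embedding the configuration.

    Recording-level and load-series results may be mixed; absent values
    (e.g. a series with no detected threshold) are written as explicit
    ``null`` fields, never omitted.
    """
    if not results:
        raise DataError("refusing to write an empty report")
    config = config or AnalysisConfig()
    doc: dict = {"config": config.to_dict(), "recordings": [], "load_series": []}
    for item in results:
        if isinstance(item, TremorPeakResult):
            doc["recordings"].append(item.to_dict())
        elif isinstance(item, LoadSeriesResult):
            doc["load_series"].append(item.to_dict())
        else:
            raise DataError(f"cannot report object of type {type(item).__name__}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    logger.info("wrote report %s", path)


def read_report(path: str | Path) -> dict:
    """Read a report written by :func:`write_report` back as a dictionary."""
    with open(path) as fh:
        return json.load(fh)


def write_scenario(
    members,
    out_dir: str | Path,
) -> Path:
    """Write a simulated cohort to a directory tree.

    Each subject gets one CSV + sidecar per recording under
    ``<out>/<subject_id>/``, and ``<out>/ground_truth.json`` stores every
    generative profile (frequency, threshold, amplitudes) for test harnesses.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = []
    for member in members:
        subj_dir = out_dir / member.profile.subject_id
        for rec in list(member.position_recordings) + list(member.load_recordings):
            lbl = rec.label
            stem = lbl.condition
            if lbl.condition == "leg_press":
                stem = f"leg_press_{int(lbl.load_kg):03d}kg"
            write_recording(rec, subj_dir / f"{stem}.csv")
        p = member.profile
        truth.append(
            {
                "subject_id": p.subject_id,
                "tremor_frequency_hz": p.tremor_frequency_hz,
                "threshold_kg": p.threshold_kg,
                "amplitude_at_threshold": p.amplitude_at_threshold,
                "amplitude_gain_per_kg": p.amplitude_gain_per_kg,
                "standing_amplitude": p.standing_amplitude,
                "noise_floor": p.noise_floor,
                "white_noise_sd": p.white_noise_sd,
                "seated_tremor": p.seated_tremor,
            }
        )
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return out_dir
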