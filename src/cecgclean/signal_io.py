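"""Data model and on-disk formats for capacitive-ECG records.

A record is a plain-text signal file (one voltage value per line, an
optional leading time column is ignored) plus a JSON sidecar carrying the
sampling rate, record id and any annotations (R-peak sample indices and
labelled intervals).  Per-segment keep/eliminate masks travel as a small
CSV table.  All indices are 0-based and all intervals half-open
``[start, end)``: a segment of ``SL`` samples starting at ``s`` covers
samples ``s .. s+SL-1``.

Amplitudes are interpreted in volts throughout; the coarse-artifact
criterion and the ``C1`` threshold constant are dimensional, so records in
other units must be rescaled on load (``scale`` argument).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError

__all__ = [
    "TimeSeries",
    "Annotation",
    "load_record",
    "save_record",
    "load_mask",
]

#: allowed labels for annotated intervals
INTERVAL_LABELS = ("useful", "useless", "coarse", "slow")

#: allowed per-segment elimination reasons in mask tables
MASK_REASONS = ("kept", "coarse", "adjacent", "slow")


@dataclass(frozen=True)
class TimeSeries:
    """A single-channel voltage time series.

    Parameters
    ----------
    samples : array-like of float
        Sample values in volts.
    fs : float
        Sampling rate in Hz, strictly positive.
    id : str
        Free-text record identifier.
    """

    samples: np.ndarray
    fs: float
    id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("samples must all be finite")
        if not (self.fs > 0):
            raise ValidationError(f"fs must be > 0, got {self.fs}")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n / self.fs

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


@dataclass(frozen=True)
class Annotation:
    """R-peak indices and labelled intervals for a record.

    ``r_peaks`` are strictly increasing 0-based sample indices; each
    interval is ``(start, end, label)`` with a half-open sample range and
    label drawn from :data:`INTERVAL_LABELS`.
    """

    r_peaks: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    intervals: tuple = ()

    def __post_init__(self) -> None:
        peaks = np.asarray(self.r_peaks, dtype=int)
        object.__setattr__(self, "r_peaks", peaks)
        if peaks.size and np.any(np.diff(peaks) <= 0):
            raise ValidationError("r_peaks must be strictly increasing")
        ivs = []
        for start, end, label in self.intervals:
            start, end = int(start), int(end)
            if end < start:
                raise ValidationError(f"interval ({start}, {end}) has negative length")
            if label not in INTERVAL_LABELS:
                raise ValidationError(f"unknown interval label {label!r}")
            ivs.append((start, end, str(label)))
        object.__setattr__(self, "intervals", tuple(ivs))

    def validate_against(self, n: int) -> None:
        """Check all indices lie within ``[0, n)``."""
        if self.r_peaks.size and (self.r_peaks.min() < 0 or self.r_peaks.max() >= n):
            raise ValidationError(f"r_peak index out of range for N={n}")
        for start, end, _ in self.intervals:
            if start < 0 or end > n:
                raise ValidationError(f"interval ({start}, {end}) out of range for N={n}")


def _parse_signal_file(path: Path, scale: float) -> np.ndarray:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            try:
                # optional time column: the value is the last field
                values.append(float(fields[-1]))
            except ValueError:
                raise ParseError(f"{path}: non-numeric value on line {lineno}: {line!r}") from None
    if not values:
        raise ParseError(f"{path}: no samples found")
    return np.asarray(values, dtype=float) * scale


def load_record(
    signal_path: str | Path,
    sidecar_path: str | Path | None = None,
    fs_override: float | None = None,
    scale: float = 1.0,
) -> tuple[TimeSeries, Annotation | None]:
    """Read a signal file and its optional JSON sidecar.

    The sampling rate comes from the sidecar's ``fs`` field unless
    ``fs_override`` is given (the override wins).  ``scale`` multiplies the
    raw values, converting records stored in units other than volts.

    Returns ``(series, annotation)``; ``annotation`` is ``None`` when the
    sidecar is absent or carries no annotation fields.
    """
    signal_path = Path(signal_path)
    if sidecar_path is None:
        candidate = signal_path.with_suffix(".json")
        sidecar_path = candidate if candidate.exists() else None

    meta: dict = {}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta = json.load(fh)

    fs = fs_override if fs_override is not None else meta.get("fs")
    if fs is None:
        raise ConfigurationError(
            f"{signal_path}: sampling rate unavailable; provide a sidecar with 'fs' or fs_override"
        )

    samples = _parse_signal_file(signal_path, scale)
    series = TimeSeries(samples, fs=float(fs), id=str(meta.get("id", signal_path.stem)))

    annotation = None
    if "r_peaks" in meta or "intervals" in meta:
        annotation = Annotation(
            r_peaks=np.asarray(meta.get("r_peaks", []), dtype=int),
            intervals=tuple((s, e, lab) for s, e, lab in meta.get("intervals", [])),
        )
        annotation.validate_against(series.n)
    return series, annotation


def save_record(
    series: TimeSeries,
    annotation: Annotation | None = None,
    mask: pd.DataFrame | None = None,
    out_prefix: str | Path = "record",
) -> list[Path]:
    """Write a record as ``<prefix>.csv`` + ``<prefix>.json`` (+ ``<prefix>.mask.csv``).

    The signal CSV holds one ``%.17g``-formatted value per line, which
    round-trips IEEE doubles bit-exactly.  Returns the list of paths written.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []

    sig_path = out_prefix.with_suffix(".csv")
    np.savetxt(sig_path, series.samples, fmt="%.17g")
    written.append(sig_path)

    meta = {
        "fs": series.fs,
        "id": series.id,
        "r_peaks": [] if annotation is None else [int(i) for i in annotation.r_peaks],
        "intervals": []
        if annotation is None
        else [[int(s), int(e), lab] for s, e, lab in annotation.intervals],
    }
    sidecar_path = out_prefix.with_suffix(".json")
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)
    written.append(sidecar_path)

    if mask is not None:
        expected = ["segment", "start", "end", "kept", "reason"]
        if list(mask.columns) != expected:
            raise ValidationError(f"mask table must have columns {expected}")
        bad = set(mask["reason"]) - set(MASK_REASONS)
        if bad:
            raise ValidationError(f"unknown mask reasons: {sorted(bad)}")
        mask_path = out_prefix.parent / (out_prefix.name + ".mask.csv")
        mask.to_csv(mask_path, index=False)
        written.append(mask_path)
    return written


def load_mask(path: str | Path) -> pd.DataFrame:
    """Read a per-segment decision table written by :func:`save_record`."""
    mask = pd.read_csv(path, dtype={"segment": int, "start": int, "end": int, "reason": str})
    mask["kept"] = mask["kept"].astype(bool)
    return mask
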