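"""Scoring of artifact-reduction output and the standard signal metrics.

A segment's true label is operational: *useful* iff it contains at least
one annotated R peak, *useless* otherwise — the criterion experts apply
when marking capacitive ECG.  Keep/eliminate decisions against these
labels give a confusion matrix (TP = kept useful, TN = eliminated useless,
FP = kept useless, FN = eliminated useful) and the usual percentage
metrics.  Undefined metrics (zero denominator) are reported as NaN, never
silently as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import periodogram

from .errors import ValidationError
from .fluctuation import SegmentGrid
from .signal_io import TimeSeries

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "RRFeatures",
    "snr",
    "segment_useful_labels",
    "segment_confusion",
    "classification_metrics",
    "r_peak_retention",
    "rr_features",
    "band_power_fractions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Percentage metrics; NaN marks an undefined (zero-denominator) entry."""

    accuracy: float
    sensitivity: float
    specificity: float
    positive_prediction: float
    negative_prediction: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "positive_prediction": self.positive_prediction,
            "negative_prediction": self.negative_prediction,
        }


@dataclass(frozen=True)
class RRFeatures:
    """Beat-interval features; ``pnn50`` is the standard successive-difference
    reading, ``pnn50_literal`` the share of RR intervals exceeding 50 ms."""

    rr_s: np.ndarray
    hr_bpm: np.ndarray
    pnn50: float
    pnn50_literal: float


def _intervals_mask(n: int, intervals: Sequence) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for iv in intervals:
        start, end = int(iv[0]), int(iv[1])
        mask[start:end] = True
    return mask


def snr(series: TimeSeries, useful_intervals: Sequence) -> float:
    """``10 * log10(Ps / Pn)`` between useful and useless signal power.

    Power is the mean square of the samples in each class.  NaN (with a
    warning) when either class is empty or the useless power is zero.
    """
    x = series.samples
    useful = _intervals_mask(series.n, useful_intervals)
    if not useful.any() or useful.all():
        warnings.warn("SNR undefined: one of the classes is empty", UserWarning)
        return float("nan")
    ps = float(np.mean(np.square(x[useful])))
    pn = float(np.mean(np.square(x[~useful])))
    if pn == 0.0:
        warnings.warn("SNR undefined: zero useless-class power", UserWarning)
        return float("nan")
    return 10.0 * np.log10(ps / pn)


def segment_useful_labels(r_peaks: np.ndarray, grid: SegmentGrid) -> np.ndarray:
    """True where a segment contains at least one R peak."""
    peaks = np.asarray(r_peaks, dtype=int)
    bounds = grid.segment_bounds()
    return np.array([bool(np.any((peaks >= s) & (peaks < e))) for s, e in bounds])


def _peaks_of(truth) -> np.ndarray:
    return np.asarray(getattr(truth, "r_peaks", truth), dtype=int)


def segment_confusion(kept: np.ndarray, truth, grid: SegmentGrid) -> ConfusionCounts:
    """Confusion counts of keep/eliminate decisions against R-peak truth.

    ``truth`` may be a GroundTruth, an Annotation, or a bare index array.
    """
    kept = np.asarray(kept, dtype=bool)
    if kept.size != grid.n_segments:
        raise ValidationError("decisions are not aligned with the grid")
    peaks = _peaks_of(truth)
    if peaks.size and peaks.max() >= grid.n:
        raise ValidationError("R-peak index beyond the gridded series")
    useful = segment_useful_labels(peaks, grid)
    return ConfusionCounts(
        tp=int(np.sum(kept & useful)),
        fp=int(np.sum(kept & ~useful)),
        tn=int(np.sum(~kept & ~useful)),
        fn=int(np.sum(~kept & useful)),
    )


def _ratio(num: int, den: int) -> float:
    return float("nan") if den == 0 else 100.0 * num / den


def classification_metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity and the two predictive values, in %."""
    c = counts
    return MetricSet(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.fp + c.tn),
        positive_prediction=_ratio(c.tp, c.tp + c.fp),
        negative_prediction=_ratio(c.tn, c.tn + c.fn),
    )


def r_peak_retention(
    kept: np.ndarray, r_peaks: np.ndarray, grid: SegmentGrid
) -> tuple[float, float]:
    """Percentage of R peaks falling in kept segments, and its complement.

    Peaks beyond the segmented span (the trailing remainder) are never
    eliminated and count as preserved.
    """
    peaks = np.asarray(r_peaks, dtype=int)
    if peaks.size == 0:
        warnings.warn("R-peak retention undefined: no peaks", UserWarning)
        return float("nan"), float("nan")
    kept = np.asarray(kept, dtype=bool)
    sample_ok = np.ones(grid.n, dtype=bool)
    for (start, end), keep in zip(grid.segment_bounds(), kept):
        if not keep:
            sample_ok[start:end] = False
    preserved = 100.0 * float(np.mean(sample_ok[peaks]))
    return preserved, 100.0 - preserved


def rr_features(
    r_peaks: np.ndarray,
    fs: float,
    index_map: np.ndarray | None = None,
) -> RRFeatures:
    """RR intervals, instantaneous HR and pNN50 from R-peak indices.

    ``HR_i = 60 / RR_i`` with ``RR_i`` in seconds.  When ``index_map`` (the
    original index of every surviving sample of a cleaned record) is given,
    peak indices refer to the original series and any RR interval spanning
    an eliminated gap is excluded from both HR and pNN50.

    pNN50 is the percentage of successive RR-difference magnitudes above
    50 ms (both differenced intervals must be gap-free); the looser
    share-of-RR-intervals-above-50-ms reading is reported alongside.
    """
    peaks = np.asarray(r_peaks, dtype=int)
    if peaks.size < 2:
        raise ValidationError("need at least 2 R peaks for RR intervals")
    rr = np.diff(peaks) / fs
    valid = np.ones(rr.size, dtype=bool)
    if index_map is not None:
        index_map = np.asarray(index_map, dtype=int)
        pos = np.searchsorted(index_map, peaks)
        if np.any(pos >= index_map.size) or np.any(index_map[pos] != peaks):
            raise ValidationError("an R peak does not survive in the cleaned record")
        valid = np.diff(pos) == np.diff(peaks)  # no eliminated sample in between

    rr_valid = rr[valid]
    if rr_valid.size == 0:
        raise ValidationError("no gap-free RR interval remains")
    hr = 60.0 / rr_valid

    if peaks.size < 3:
        raise ValidationError("need at least 3 R peaks for pNN50")
    pair_ok = valid[:-1] & valid[1:]
    diffs = np.abs(np.diff(rr))[pair_ok]
    pnn50 = float("nan") if diffs.size == 0 else 100.0 * float(np.mean(diffs > 0.050))
    literal = 100.0 * float(np.mean(rr_valid > 0.050))
    return RRFeatures(rr_s=rr_valid, hr_bpm=hr, pnn50=pnn50, pnn50_literal=literal)


def band_power_fractions(
    series: TimeSeries, bands: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Periodogram power split across ``bands`` (Hz), normalized to 100 %."""
    nyquist = series.fs / 2.0
    for lo, hi in bands:
        if lo < 0 or hi > nyquist or hi <= lo:
            raise ValidationError(f"band ({lo}, {hi}) outside (0, {nyquist}) Hz")
    lowest = min(lo for lo, _ in bands if lo > 0) if any(lo > 0 for lo, _ in bands) else None
    if lowest is not None and series.duration < 2.0 / lowest:
        raise ValidationError("series shorter than 2 periods of the lowest band edge")
    freqs, pxx = periodogram(series.samples, fs=series.fs)
    powers = np.array([float(pxx[(freqs >= lo) & (freqs < hi)].sum()) for lo, hi in bands])
    total = powers.sum()
    if total == 0.0:
        raise ValidationError("no spectral power in the requested bands")
    return 100.0 * powers / total
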