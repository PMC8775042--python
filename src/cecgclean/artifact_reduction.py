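"""Threshold-based elimination of artifact segments from capacitive ECG.

The method classifies each fixed-length segment of the record as useful or
artifact from its detrended fluctuation ``F_D``:

* a global criterion ``(max(x) - min(x))/2 - sqrt(M) > 1`` (volts, with
  ``M`` the uncentralized second moment) detects whether sparse
  high-amplitude coarse artifacts are present at all;
* ``TH1``, built from the record's amplitude statistics and the ``F_D``
  distribution, eliminates coarse-artifact segments (``F_D > TH1``);
* ``TH2 = TH1/2`` guards immediate neighbours of coarse segments against
  artifacts spilling across a segment boundary: a neighbour is eliminated
  when the coarse segment's ``F_D`` exceeds its own by more than ``TH2``
  (or, under the alternative ``own`` rule, when the neighbour's own
  ``F_D`` exceeds ``TH2``);
* ``TH3 = 0.1`` eliminates slow-changing artifacts — segments whose
  profile hugs its linear trend (``F_D <= TH3``) — guarded by
  ``mean(F_D) - SD(F_D) > TH3`` so that low-amplitude but clean records
  are not gutted.

Elimination means exclusion: kept segments are concatenated and an index
map records where each surviving sample came from, so downstream beat
intervals spanning a gap can be flagged.

Both a batch mode and an online mode are provided.  Online, the first
``init_seconds`` of signal seed the statistics; every subsequent full
segment extends the ``F_D`` collection, the thresholds are refreshed, and
the new segment's decision is emitted immediately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateSignalError, ValidationError
from .fluctuation import (
    FluctuationProfile,
    SegmentGrid,
    detrend_segment,
    fluctuation_series,
    make_segment_grid,
    segment_fluctuation,
)
from .signal_io import TimeSeries

__all__ = [
    "TH3",
    "ThresholdSet",
    "ReductionResult",
    "OnlineDecision",
    "coarse_artifact_present",
    "compute_thresholds",
    "reduce_artifacts",
    "reduce_online",
    "extract_clean",
]

#: slow-changing-artifact threshold: the fluctuation of a segment whose
#: squared deviation from its linear trend is 0.01 at every sample.
TH3 = 0.1

#: coarse-artifact presence cut, in volts (strict inequality).
COARSE_PRESENCE_LEVEL = 1.0


@dataclass(frozen=True)
class ThresholdSet:
    """Data-driven thresholds plus the record statistics they derive from.

    ``th1 = (((x_max - x_min)/2)^2 - M) * C * median(F_D)
           + (SD(F_D) + SD(x)) / (SD(F_D) * SD(x)) * C1``

    with ``M`` the uncentralized second moment of ``x`` (V^2), ``C`` an
    empirical constant (best range 0.15–0.35, units 1/V^2) and
    ``C1 = 1 V``.  Standard deviations are the unbiased (n-1) form.
    """

    th1: float
    c: float
    c1: float
    x_max: float
    x_min: float
    second_moment: float
    median_fd: float
    sd_fd: float
    sd_x: float
    mean_fd: float

    @property
    def th2(self) -> float:
        return self.th1 / 2.0

    @property
    def th3(self) -> float:
        return TH3

    @property
    def rms(self) -> float:
        """sqrt of the second moment, in volts."""
        return float(np.sqrt(self.second_moment))

    def as_dict(self) -> dict:
        return {
            "th1": self.th1,
            "th2": self.th2,
            "th3": self.th3,
            "c": self.c,
            "c1": self.c1,
            "x_max": self.x_max,
            "x_min": self.x_min,
            "second_moment": self.second_moment,
            "rms": self.rms,
            "median_fd": self.median_fd,
            "sd_fd": self.sd_fd,
            "sd_x": self.sd_x,
            "mean_fd": self.mean_fd,
        }


@dataclass(frozen=True)
class ReductionResult:
    """Per-segment decisions, the thresholds used, and the cleaned series."""

    grid: SegmentGrid
    fd: np.ndarray
    kept: np.ndarray
    reasons: tuple
    thresholds: ThresholdSet | None
    coarse_present: bool
    coarse_statistic: float
    cleaned: TimeSeries
    index_map: np.ndarray
    degenerate: bool = False

    @property
    def n_eliminated(self) -> int:
        return int((~self.kept).sum())

    def mask_frame(self) -> pd.DataFrame:
        """Decision table in the on-disk mask format."""
        bounds = self.grid.segment_bounds()
        return pd.DataFrame(
            {
                "segment": np.arange(self.grid.n_segments),
                "start": bounds[:, 0],
                "end": bounds[:, 1],
                "kept": self.kept,
                "reason": list(self.reasons),
            }
        )


@dataclass(frozen=True)
class OnlineDecision:
    """One emitted decision of the streaming reducer."""

    segment: int
    start: int
    fd: float
    kept: bool
    reason: str


def coarse_artifact_present(series: TimeSeries | np.ndarray) -> tuple[bool, float]:
    """Check whether the record carries sparse high-amplitude coarse artifacts.

    The statistic is ``(max(x) - min(x))/2 - sqrt(M)`` with
    ``M = mean(x^2)``.  Sparse multi-volt transients stretch the range
    while barely moving the RMS, pushing the statistic above 1 V; dense
    equal-magnitude swings (where range/2 ~ RMS) and quiet records stay
    below.  Returns ``(statistic > 1, statistic)``.
    """
    x = series.samples if isinstance(series, TimeSeries) else np.asarray(series, dtype=float)
    if x.size < 1:
        raise ValidationError("empty series")
    second_moment = float(np.mean(np.square(x)))
    statistic = (float(x.max()) - float(x.min())) / 2.0 - float(np.sqrt(second_moment))
    return statistic > COARSE_PRESENCE_LEVEL, statistic


def compute_thresholds(
    series: TimeSeries | np.ndarray,
    profile: FluctuationProfile | np.ndarray,
    c: float = 0.25,
    c1: float = 1.0,
) -> ThresholdSet:
    """Derive ``TH1`` (and with it TH2/TH3) from a record and its F_D values.

    Raises :class:`DegenerateSignalError` when either the signal or its
    fluctuation series has zero spread — reduction should then be skipped.
    """
    x = series.samples if isinstance(series, TimeSeries) else np.asarray(series, dtype=float)
    fd = profile.values if isinstance(profile, FluctuationProfile) else np.asarray(profile, float)
    if fd.size == 0:
        raise ValidationError("empty fluctuation profile")
    if not (c > 0):
        raise ValidationError(f"C must be positive, got {c}")

    sd_x = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    sd_fd = float(np.std(fd, ddof=1)) if fd.size > 1 else 0.0
    if sd_x == 0.0 or sd_fd == 0.0:
        raise DegenerateSignalError(
            "zero-variance signal or fluctuation series; skip reduction for this record"
        )
    x_max, x_min = float(x.max()), float(x.min())
    second_moment = float(np.mean(np.square(x)))
    median_fd = float(np.median(fd))
    th1 = (((x_max - x_min) / 2.0) ** 2 - second_moment) * c * median_fd + (
        (sd_fd + sd_x) / (sd_fd * sd_x)
    ) * c1
    return ThresholdSet(
        th1=th1,
        c=c,
        c1=c1,
        x_max=x_max,
        x_min=x_min,
        second_moment=second_moment,
        median_fd=median_fd,
        sd_fd=sd_fd,
        sd_x=sd_x,
        mean_fd=float(np.mean(fd)),
    )


def _grid_blocks(grid: SegmentGrid) -> list[tuple[int, int]]:
    """Index ranges of segments that are contiguous passes over the signal.

    Adjacency (the TH2 spill-over rule) only makes sense within one pass:
    a bidirectional grid holds a forward pass followed by an end-aligned
    pass of equal size.
    """
    n = grid.n_segments
    if grid.mode == "bidirectional":
        return [(0, n // 2), (n // 2, n)]
    return [(0, n)]


def _decide_segments(
    fd: np.ndarray,
    thresholds: ThresholdSet,
    coarse_present: bool,
    blocks: Sequence[tuple[int, int]],
    adjacency: str = "difference",
) -> tuple[np.ndarray, list[str]]:
    """Apply the three threshold rules to a fluctuation series.

    ``adjacency='difference'`` (default) eliminates a neighbour of a
    coarse segment when the coarse segment's ``F_D`` exceeds the
    neighbour's by more than ``TH2`` — this catches a small artifact
    fragment spilling into an otherwise quiet neighbour, whose own ``F_D``
    stays low.  ``adjacency='own'`` is the alternative reading that
    compares the neighbour's own ``F_D`` with ``TH2``.
    """
    if adjacency not in ("own", "difference"):
        raise ValidationError(f"unknown adjacency rule {adjacency!r}")
    n = fd.size
    reasons = ["kept"] * n

    if coarse_present:
        coarse = fd > thresholds.th1
        for j in np.flatnonzero(coarse):
            reasons[j] = "coarse"
        # single-hop spill-over: only direct neighbours of coarse segments
        for lo, hi in blocks:
            for j in np.flatnonzero(coarse[lo:hi]) + lo:
                for nb in (j - 1, j + 1):
                    if nb < lo or nb >= hi or reasons[nb] != "kept":
                        continue
                    if adjacency == "own":
                        hit = fd[nb] > thresholds.th2
                    else:
                        hit = fd[j] - fd[nb] > thresholds.th2
                    if hit:
                        reasons[nb] = "adjacent"

    if thresholds.mean_fd - thresholds.sd_fd > thresholds.th3:
        for j in range(n):
            if reasons[j] == "kept" and fd[j] <= thresholds.th3:
                reasons[j] = "slow"

    kept = np.array([r == "kept" for r in reasons])
    return kept, reasons


def extract_clean(
    series: TimeSeries,
    grid: SegmentGrid,
    kept: np.ndarray,
) -> tuple[TimeSeries, np.ndarray]:
    """Concatenate kept segments of ``series``.

    A sample survives unless some eliminated segment covers it (overlapping
    passes of a bidirectional grid may each veto a sample); samples beyond
    the segmented span (the trailing remainder of a forward grid) are never
    eliminated.  Returns the cleaned series and the strictly increasing map
    from cleaned-sample position to original index.
    """
    kept = np.asarray(kept, dtype=bool)
    if kept.size != grid.n_segments:
        raise ValidationError("decisions are not aligned with the grid")
    sample_ok = np.ones(series.n, dtype=bool)
    bounds = grid.segment_bounds()
    for (start, end), keep in zip(bounds, kept):
        if not keep:
            sample_ok[start:end] = False
    index_map = np.flatnonzero(sample_ok)
    if index_map.size == 0:
        cleaned_samples = np.empty(0, dtype=float)
        cleaned = TimeSeries.__new__(TimeSeries)  # bypass N>=1 check for the empty result
        object.__setattr__(cleaned, "samples", cleaned_samples)
        object.__setattr__(cleaned, "fs", series.fs)
        object.__setattr__(cleaned, "id", series.id + "-clean")
    else:
        cleaned = TimeSeries(series.samples[index_map], fs=series.fs, id=series.id + "-clean")
    return cleaned, index_map


def reduce_artifacts(
    series: TimeSeries,
    sl_seconds: float = 0.5,
    c: float = 0.25,
    c1: float = 1.0,
    form: str = "rms",
    grid_mode: str = "auto",
    adjacency: str = "difference",
) -> ReductionResult:
    """Batch artifact reduction of one record.

    Builds the segment grid (``SL = round(sl_seconds * fs)`` samples),
    computes the fluctuation profile and thresholds, applies the
    coarse/adjacent rules when the coarse-presence criterion fires and the
    slow-artifact rule when its guard holds, and returns the decisions
    together with the cleaned series.

    Degenerate (zero-variance) records are returned unreduced with
    ``degenerate=True`` and a warning instead of raising, so batch
    pipelines keep running.
    """
    sl = int(round(sl_seconds * series.fs))
    if sl < 2:
        raise ValidationError(f"segment length {sl_seconds}s is under 2 samples at fs={series.fs}")
    if series.n // sl < 2:
        raise ValidationError("record is shorter than 2 segments; nothing to classify")
    grid = make_segment_grid(series.n, sl, mode=grid_mode, fs=series.fs)
    prof = fluctuation_series(series, grid, form=form)
    present, statistic = coarse_artifact_present(series)

    try:
        thresholds = compute_thresholds(series, prof, c=c, c1=c1)
    except DegenerateSignalError as err:
        warnings.warn(str(err), RuntimeWarning)
        kept = np.ones(grid.n_segments, dtype=bool)
        cleaned, index_map = extract_clean(series, grid, kept)
        return ReductionResult(
            grid=grid,
            fd=prof.values,
            kept=kept,
            reasons=tuple(["kept"] * grid.n_segments),
            thresholds=None,
            coarse_present=present,
            coarse_statistic=statistic,
            cleaned=cleaned,
            index_map=index_map,
            degenerate=True,
        )

    kept, reasons = _decide_segments(
        prof.values, thresholds, present, _grid_blocks(grid), adjacency=adjacency
    )
    cleaned, index_map = extract_clean(series, grid, kept)
    return ReductionResult(
        grid=grid,
        fd=prof.values,
        kept=kept,
        reasons=tuple(reasons),
        thresholds=thresholds,
        coarse_present=present,
        coarse_statistic=statistic,
        cleaned=cleaned,
        index_map=index_map,
    )


def reduce_online(
    chunks: Iterable[TimeSeries | np.ndarray],
    fs: float | None = None,
    init_seconds: float = 50.0,
    sl_seconds: float = 0.5,
    c: float = 0.25,
    c1: float = 1.0,
    form: str = "rms",
    adjacency: str = "difference",
) -> Iterator[OnlineDecision]:
    """Streaming artifact reduction.

    The first ``init_seconds`` of signal are buffered and processed exactly
    as in batch mode (forward grid), providing the initial statistics; the
    buffered segments' decisions are emitted first.  Each subsequent full
    segment appends its ``F_D`` to the running collection, the amplitude
    statistics and thresholds are refreshed over everything seen so far
    (the running mean of ``x`` is updated incrementally; old values are
    never discarded), and the new segment's decision is emitted.  The
    spill-over rule can only act causally here: a segment following a
    coarse-eliminated one is checked against ``TH2``, but an
    already-emitted predecessor is never retracted.

    Raises :class:`ValidationError` if the stream ends before
    ``init_seconds`` of signal arrived.
    """
    chunk_iter = iter(chunks)
    first_arrays: list[np.ndarray] = []
    for chunk in chunk_iter:
        if isinstance(chunk, TimeSeries):
            if fs is None:
                fs = chunk.fs
            first_arrays.append(chunk.samples)
        else:
            first_arrays.append(np.asarray(chunk, dtype=float))
        break
    if fs is None:
        raise ValidationError("fs must be given when streaming bare arrays")

    sl = int(round(sl_seconds * fs))
    init_n = int(round(init_seconds * fs))

    def _arrays() -> Iterator[np.ndarray]:
        yield from first_arrays
        for chk in chunk_iter:
            yield chk.samples if isinstance(chk, TimeSeries) else np.asarray(chk, dtype=float)

    arrays = _arrays()
    buffer = np.empty(0, dtype=float)
    for arr in arrays:
        buffer = np.concatenate([buffer, arr])
        if buffer.size >= init_n:
            break
    if buffer.size < init_n:
        raise ValidationError(
            f"stream provides {buffer.size} samples, fewer than the "
            f"{init_n}-sample ({init_seconds}s) initialization window"
        )

    init = TimeSeries(buffer[:init_n], fs=fs, id="online-init")
    batch = reduce_artifacts(
        init, sl_seconds=sl_seconds, c=c, c1=c1, form=form, grid_mode="forward",
        adjacency=adjacency,
    )
    bounds = batch.grid.segment_bounds()
    for j in range(batch.grid.n_segments):
        yield OnlineDecision(
            segment=j,
            start=int(bounds[j, 0]),
            fd=float(batch.fd[j]),
            kept=bool(batch.kept[j]),
            reason=batch.reasons[j],
        )

    # running aggregates over all samples seen so far
    seen = buffer[:init_n]
    count = seen.size
    total = float(seen.sum())
    total_sq = float(np.square(seen).sum())
    x_min, x_max = float(seen.min()), float(seen.max())
    fd_list = list(batch.fd)
    prev_reason = batch.reasons[-1]
    seg_index = batch.grid.n_segments
    consumed = batch.grid.n_segments * sl  # segmented span of the init window

    pending = buffer[consumed:]
    exhausted = False
    while True:
        while pending.size < sl and not exhausted:
            nxt = next(arrays, None)
            if nxt is None:
                exhausted = True
            else:
                pending = np.concatenate([pending, nxt])
        if pending.size < sl:
            break
        seg = pending[:sl]
        pending = pending[sl:]

        start = consumed
        sum_before = total
        count += sl
        total += float(seg.sum())
        total_sq += float(np.square(seg).sum())
        x_min = min(x_min, float(seg.min()))
        x_max = max(x_max, float(seg.max()))
        mean = total / count

        # profile values inside the new segment, continued from the running sums;
        # the constant and linear parts contributed by the running mean are
        # absorbed by the detrend
        global_idx = np.arange(start + 1, start + sl + 1, dtype=float)
        seg_profile = sum_before + np.cumsum(seg) - mean * global_idx
        residuals, *_ = detrend_segment(seg_profile)
        fd = segment_fluctuation(residuals, form=form)
        fd_list.append(fd)
        consumed += sl

        fd_arr = np.asarray(fd_list)
        sd_x_sq = max(0.0, (total_sq - count * mean * mean) / (count - 1))
        sd_x = float(np.sqrt(sd_x_sq))
        sd_fd = float(np.std(fd_arr, ddof=1))
        statistic = (x_max - x_min) / 2.0 - float(np.sqrt(total_sq / count))
        present = statistic > COARSE_PRESENCE_LEVEL

        reason = "kept"
        if sd_x > 0 and sd_fd > 0:
            median_fd = float(np.median(fd_arr))
            second_moment = total_sq / count
            th1 = (((x_max - x_min) / 2.0) ** 2 - second_moment) * c * median_fd + (
                (sd_fd + sd_x) / (sd_fd * sd_x)
            ) * c1
            th2 = th1 / 2.0
            if present and fd > th1:
                reason = "coarse"
            elif present and prev_reason == "coarse":
                if adjacency == "own":
                    hit = fd > th2
                else:
                    hit = fd_list[-2] - fd > th2
                if hit:
                    reason = "adjacent"
            if reason == "kept" and float(np.mean(fd_arr)) - sd_fd > TH3 and fd <= TH3:
                reason = "slow"

        prev_reason = reason
        yield OnlineDecision(
            segment=seg_index, start=start, fd=fd, kept=reason == "kept", reason=reason
        )
        seg_index += 1
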