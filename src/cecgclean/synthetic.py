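"""Synthetic capacitive-ECG records with ground truth.

Capacitive (through-clothing) ECG differs from clinical ECG in three ways
this generator emulates: the useful signal is small (R-peak amplitudes of
a few hundred millivolts to a couple of volts), movements superimpose
sparse coarse artifacts of several volts, and slow-changing artifacts of
amplitude comparable to the ECG — band-limited below ~15 Hz, where the ECG
spectrum also lives — replace the signal over whole intervals so that no
R peak is discernible there.

The ECG itself is a per-beat sum of localized analytic bumps approximating
the P-QRS-T morphology, placed at jittered RR intervals; no recorded
template is used.  Ground truth records every R-peak index and a typed
partition of the record into useful / coarse / slow intervals.  Slow
artifacts *replace* the ECG (they model stretches the experts would call
useless); coarse artifacts are *superimposed* on it.  Everything is driven
by one seeded generator, so equal seeds give bit-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .signal_io import Annotation, TimeSeries

__all__ = [
    "CoarseParams",
    "SlowParams",
    "SyntheticConfig",
    "GroundTruth",
    "generate_cecg",
    "inject_coarse_artifacts",
    "inject_slow_artifacts",
    "protocol_schedule",
    "band_limited_noise",
]

#: supported coarse-burst shapes
COARSE_SHAPES = ("spike_train", "step", "clip")


@dataclass(frozen=True)
class CoarseParams:
    """Movement-burst parameters.

    ``shapes`` defaults to spike trains alone: movement artifacts present
    as dense high-amplitude peaks on a saturating low-frequency coupling
    swing.  ``step`` (a sustained level shift) and ``clip`` (a held rail
    offset) are available but model a different failure mode — a constant
    plateau is invisible to a linear-detrend fluctuation statistic away
    from its edges.
    """

    count: int = 10
    amp_range: tuple[float, float] = (2.0, 8.0)  # volts
    duration_range: tuple[float, float] = (0.2, 2.0)  # seconds
    shapes: tuple[str, ...] = ("spike_train",)

    def __post_init__(self) -> None:
        unknown = set(self.shapes) - set(COARSE_SHAPES)
        if unknown:
            raise ValidationError(f"unknown coarse shapes: {sorted(unknown)}")


@dataclass(frozen=True)
class SlowParams:
    """Slow-changing-artifact parameters: 0.5-15 Hz noise replacing the ECG."""

    count: int = 4
    duration_range: tuple[float, float] = (2.0, 8.0)  # seconds
    band: tuple[float, float] = (0.5, 15.0)  # Hz
    amplitude_ratio: float = 1.0  # interval RMS relative to the ECG RMS


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration; defaults emulate a bed-style recording."""

    fs: float = 400.0
    duration: float = 300.0  # seconds
    hr_bpm: float = 70.0
    rr_jitter: float = 0.05  # relative SD of RR intervals
    ecg_amp: float = 0.5  # R-peak amplitude, volts
    baseline_noise_sd: float = 0.02  # volts
    coarse: CoarseParams = field(default_factory=CoarseParams)
    slow: SlowParams = field(default_factory=SlowParams)
    protocol: str = "none"  # {"none", "bed"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValidationError("fs and duration must be positive")
        if self.fs * self.duration < 2 * round(0.5 * self.fs):
            raise ValidationError("record must span at least 2 segments at SL=0.5 s")
        if self.protocol not in ("none", "bed"):
            raise ValidationError(f"unknown protocol {self.protocol!r}")


@dataclass(frozen=True)
class GroundTruth:
    """R-peak indices plus a typed interval partition of ``[0, n)``.

    Artifact intervals never overlap each other and contain no R peak (the
    generator removes peaks it overwrites or buries); gaps between them
    are labelled ``useful``.
    """

    r_peaks: np.ndarray
    intervals: tuple
    n: int

    def artifact_intervals(self, label: str | None = None) -> list[tuple[int, int, str]]:
        out = [iv for iv in self.intervals if iv[2] != "useful"]
        if label is not None:
            out = [iv for iv in out if iv[2] == label]
        return out

    def useful_intervals(self) -> list[tuple[int, int, str]]:
        return [iv for iv in self.intervals if iv[2] == "useful"]

    def to_annotation(self) -> Annotation:
        return Annotation(r_peaks=self.r_peaks, intervals=self.intervals)


def _partition(n: int, artifacts: list[tuple[int, int, str]]) -> tuple:
    """Fill the gaps between artifact intervals with ``useful`` labels."""
    out: list[tuple[int, int, str]] = []
    cursor = 0
    for start, end, label in sorted(artifacts):
        if start < cursor:
            raise ValidationError("artifact intervals overlap")
        if start > cursor:
            out.append((cursor, start, "useful"))
        out.append((start, end, label))
        cursor = end
    if cursor < n:
        out.append((cursor, n, "useful"))
    return tuple(out)


def _drop_peaks_inside(peaks: np.ndarray, intervals: list[tuple[int, int, str]]) -> np.ndarray:
    keep = np.ones(peaks.size, dtype=bool)
    for start, end, _ in intervals:
        keep &= ~((peaks >= start) & (peaks < end))
    return peaks[keep]


def band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-RMS Gaussian noise spectrally confined to ``band`` (Hz).

    White noise is shaped in the frequency domain: rFFT bins outside the
    band are zeroed and the result transformed back.
    """
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum[(freqs < band[0]) | (freqs > band[1])] = 0.0
    shaped = np.fft.irfft(spectrum, n=n)
    rms = float(np.sqrt(np.mean(np.square(shaped))))
    if rms == 0.0:
        raise ValidationError(f"band {band} contains no FFT bin for n={n}, fs={fs}")
    return shaped / rms


# P-QRS-T as localized Gaussian bumps: (offset s, width s, relative amplitude)
_BEAT_BUMPS = (
    (-0.20, 0.025, 0.15),  # P
    (-0.035, 0.012, -0.12),  # Q
    (0.0, 0.014, 1.0),  # R
    (0.035, 0.012, -0.20),  # S
    (0.30, 0.060, 0.30),  # T
)


def _render_ecg(peak_times: np.ndarray, n: int, fs: float, amp: float) -> np.ndarray:
    x = np.zeros(n)
    half_window = 0.45  # seconds around each R peak that the bumps cover
    for t0 in peak_times:
        lo = max(0, int((t0 - half_window) * fs))
        hi = min(n, int((t0 + half_window) * fs) + 1)
        t = np.arange(lo, hi) / fs - t0
        beat = np.zeros(hi - lo)
        for offset, width, rel in _BEAT_BUMPS:
            beat += rel * np.exp(-0.5 * ((t - offset) / width) ** 2)
        x[lo:hi] += amp * beat
    return x


def _place_intervals(
    rng: np.random.Generator,
    n: int,
    fs: float,
    count: int,
    duration_range: tuple[float, float],
    occupied: list[tuple[int, int]],
    margin_s: float = 1.0,
) -> list[tuple[int, int]]:
    """Draw ``count`` non-overlapping sample intervals avoiding ``occupied``."""
    margin = int(margin_s * fs)
    placed: list[tuple[int, int]] = []
    total_needed = count * duration_range[1] * fs
    if total_needed > 0.8 * n:
        raise ValidationError("requested artifact intervals cannot fit in the record")
    for _ in range(count):
        for _attempt in range(2000):
            dur = int(rng.uniform(*duration_range) * fs)
            dur = max(dur, 1)
            if n - margin - dur <= margin:
                raise ValidationError("record too short for the requested artifact durations")
            start = int(rng.integers(margin, n - margin - dur))
            cand = (start, start + dur)
            clash = any(
                cand[0] < e + margin and s - margin < cand[1] for s, e in occupied + placed
            )
            if not clash:
                placed.append(cand)
                break
        else:
            raise ValidationError("could not place artifact intervals without overlap")
    return placed


def _osc_mix(
    rng: np.random.Generator, n_samp: int, fs: float, band: tuple[float, float], k: int = 12
) -> np.ndarray:
    """Sum of ``k`` random sinusoids in ``band`` — well defined at any length,
    unlike FFT-bin shaping, which has no bin below ``fs/n`` for short bursts."""
    t = np.arange(n_samp) / fs
    freqs = rng.uniform(band[0], band[1], size=k)
    phases = rng.uniform(0, 2 * np.pi, size=k)
    amps = rng.uniform(0.3, 1.0, size=k)
    return np.einsum(
        "k,kt->t", amps, np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
    )


def _spike_train(rng: np.random.Generator, n_samp: int, fs: float, amp: float) -> np.ndarray:
    """Movement burst: dense high-amplitude peaks on a saturating coupling swing.

    Body movement modulates the electrode coupling capacitance, producing a
    large low-frequency (~0.4-3 Hz) swing with sharper (3-20 Hz)
    transients riding on it; big movements drive the front-end toward its
    rails, so the waveform soft-saturates (crest factor near 1).  The
    burst peak is normalized to exactly ``amp``.
    """
    z = _osc_mix(rng, n_samp, fs, (0.4, 3.0)) + 0.3 * _osc_mix(rng, n_samp, fs, (3.0, 20.0))
    z = z / max(1e-12, float(np.sqrt(np.mean(np.square(z)))))
    shape = np.tanh(1.2 * z)
    return amp * shape / float(np.max(np.abs(shape)))


def _step(rng: np.random.Generator, n_samp: int, fs: float, amp: float) -> np.ndarray:
    """Sustained baseline shift with smooth edges (electrode repositioning)."""
    sign = float(rng.choice([-1.0, 1.0]))
    edge = max(2, int(0.02 * fs))
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, edge)))
    plateau = np.ones(max(0, n_samp - 2 * edge))
    shape = np.concatenate([ramp, plateau, ramp[::-1]])[:n_samp]
    return sign * amp * shape


def _clip_burst(rng: np.random.Generator, n_samp: int, fs: float, amp: float) -> np.ndarray:
    """Rail saturation: the offset drives the channel to +/-amp with ripple."""
    base = _step(rng, n_samp, fs, amp)
    ripple = 0.02 * amp * rng.standard_normal(n_samp)
    return base + ripple


def inject_coarse_artifacts(
    series: TimeSeries,
    ground_truth: GroundTruth,
    params: CoarseParams,
    rng: np.random.Generator | int,
) -> tuple[TimeSeries, GroundTruth]:
    """Superimpose high-amplitude movement bursts and update the ground truth.

    Burst positions avoid existing artifact intervals; R peaks buried under
    a burst are removed from the truth (an expert could not mark them).
    """
    if params.count == 0:
        return series, ground_truth
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    x = series.samples.copy()
    occupied = [(s, e) for s, e, _ in ground_truth.artifact_intervals()]
    spans = _place_intervals(
        rng, series.n, series.fs, params.count, params.duration_range, occupied
    )
    renderers = {"spike_train": _spike_train, "step": _step, "clip": _clip_burst}
    new_intervals = []
    for start, end in spans:
        shape = str(rng.choice(list(params.shapes)))
        amp = float(rng.uniform(*params.amp_range))
        x[start:end] += renderers[shape](rng, end - start, series.fs, amp)
        new_intervals.append((start, end, "coarse"))
    artifacts = ground_truth.artifact_intervals() + new_intervals
    peaks = _drop_peaks_inside(ground_truth.r_peaks, new_intervals)
    return (
        TimeSeries(x, fs=series.fs, id=series.id),
        GroundTruth(r_peaks=peaks, intervals=_partition(series.n, artifacts), n=series.n),
    )


def inject_slow_artifacts(
    series: TimeSeries,
    ground_truth: GroundTruth,
    params: SlowParams,
    rng: np.random.Generator | int,
    ecg_rms: float | None = None,
) -> tuple[TimeSeries, GroundTruth]:
    """Replace intervals with band-limited noise of ECG-comparable amplitude.

    ``ecg_rms`` anchors the amplitude ratio; when absent, the RMS of the
    series outside existing artifact intervals is used.
    """
    if params.count == 0:
        return series, ground_truth
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    x = series.samples.copy()
    occupied = [(s, e) for s, e, _ in ground_truth.artifact_intervals()]
    if ecg_rms is None:
        mask = np.ones(series.n, dtype=bool)
        for s, e in occupied:
            mask[s:e] = False
        ecg_rms = float(np.sqrt(np.mean(np.square(series.samples[mask]))))
    target_rms = params.amplitude_ratio * ecg_rms
    spans = _place_intervals(
        rng, series.n, series.fs, params.count, params.duration_range, occupied
    )
    new_intervals = []
    for start, end in spans:
        x[start:end] = target_rms * band_limited_noise(rng, end - start, series.fs, params.band)
        new_intervals.append((start, end, "slow"))
    artifacts = ground_truth.artifact_intervals() + new_intervals
    peaks = _drop_peaks_inside(ground_truth.r_peaks, new_intervals)
    return (
        TimeSeries(x, fs=series.fs, id=series.id),
        GroundTruth(r_peaks=peaks, intervals=_partition(series.n, artifacts), n=series.n),
    )


def protocol_schedule(
    kind: str, duration: float, move_seconds: float = 5.0
) -> list[tuple[float, float]]:
    """Movement intervals (seconds) of the scripted bed protocol.

    First half of the recording: a brief movement every 60 s.  Second
    half: lie 120 s, move 60 s, lie 120 s; when the second half is shorter
    than the full 300 s pattern the 2:1:2 rest/move/rest proportions are
    kept.  Requires ``duration >= 300`` s.
    """
    if kind != "bed":
        raise ValidationError(f"unknown protocol {kind!r}")
    if duration < 300:
        raise ValidationError("the bed protocol needs at least 300 s")
    half = duration / 2.0
    moves = [(60.0 * k, 60.0 * k + move_seconds) for k in range(1, int(half // 60) + 1)]
    second = duration - half
    if second >= 300.0:
        moves.append((half + 120.0, half + 180.0))
    else:
        moves.append((half + 0.4 * second, half + 0.6 * second))
    return moves


def generate_cecg(cfg: SyntheticConfig = SyntheticConfig()) -> tuple[TimeSeries, GroundTruth]:
    """Generate one record: ECG + noise, then slow, then coarse artifacts."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.fs * cfg.duration))

    # beat placement at jittered RR intervals
    rr_mean = 60.0 / cfg.hr_bpm
    peak_times = []
    t = rr_mean
    while t < cfg.duration - 0.5:
        peak_times.append(t)
        t += rr_mean * max(0.3, 1.0 + cfg.rr_jitter * rng.standard_normal())
    peak_times = np.asarray(peak_times)

    x = _render_ecg(peak_times, n, cfg.fs, cfg.ecg_amp)
    ecg_rms = float(np.sqrt(np.mean(np.square(x))))
    x += cfg.baseline_noise_sd * rng.standard_normal(n)

    peaks = np.round(peak_times * cfg.fs).astype(int)
    series = TimeSeries(x, fs=cfg.fs, id=f"synthetic-{cfg.seed}")
    truth = GroundTruth(r_peaks=peaks, intervals=_partition(n, []), n=n)

    series, truth = inject_slow_artifacts(series, truth, cfg.slow, rng, ecg_rms=ecg_rms)

    coarse = cfg.coarse
    if cfg.protocol == "bed":
        schedule = protocol_schedule("bed", cfg.duration)
        spans = [(int(s * cfg.fs), min(int(e * cfg.fs), n)) for s, e in schedule]
        series, truth = _inject_coarse_at(series, truth, coarse, rng, spans)
    else:
        series, truth = inject_coarse_artifacts(series, truth, coarse, rng)
    return series, truth


def _inject_coarse_at(
    series: TimeSeries,
    ground_truth: GroundTruth,
    params: CoarseParams,
    rng: np.random.Generator,
    spans: list[tuple[int, int]],
) -> tuple[TimeSeries, GroundTruth]:
    """Coarse injection at prescribed sample spans (protocol schedules)."""
    x = series.samples.copy()
    renderers = {"spike_train": _spike_train, "step": _step, "clip": _clip_burst}
    new_intervals = []
    for start, end in spans:
        shape = str(rng.choice(list(params.shapes)))
        amp = float(rng.uniform(*params.amp_range))
        x[start:end] += renderers[shape](rng, end - start, series.fs, amp)
        new_intervals.append((start, end, "coarse"))
    artifacts = ground_truth.artifact_intervals() + new_intervals
    peaks = _drop_peaks_inside(ground_truth.r_peaks, new_intervals)
    return (
        TimeSeries(x, fs=series.fs, id=series.id),
        GroundTruth(r_peaks=peaks, intervals=_partition(series.n, artifacts), n=series.n),
    )
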