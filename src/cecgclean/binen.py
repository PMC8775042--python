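"""Binarized approximate and sample entropy (BinApEn / BinSampEn).

The signal is reduced to a binary differential code — 1 where the series
increases, 0 otherwise — and entropy is estimated over ``m``-bit windows
of that code with Hamming-distance tolerance ``r``.  Because the alphabet
has only ``2^m`` symbols, the template-matching statistics collapse onto a
histogram: counting each symbol once and multiplying by a precomputed
Hamming-distance indicator matrix is exactly equivalent to the naive
pairwise window comparison, at cost ``O(N + 4^m)`` instead of ``O(N^2)``.
Amplitude artifacts affect the code only through sign changes, which makes
these estimators usable on raw artifact-laden records.

``BinApEn = Phi^m - Phi^{m+1}`` with
``Phi^m = sum_k p(k) * ln(sum_n p(n) * [hamming(k, n) <= r])``.
``BinSampEn = -10 * log10(Phi~^{m+1} / Phi~^m)`` where the tilded sums
exclude each window's self-match from both the neighbour count and its
denominator; it is undefined (NaN with a warning) when ``Phi~^m`` is zero
or the ratio is non-positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .signal_io import TimeSeries

__all__ = [
    "BinEnConfig",
    "BinEnResult",
    "binarize",
    "window_codes",
    "vector_histogram",
    "hamming_matrix",
    "phi",
    "phi_excluding_self",
    "bin_ap_en",
    "bin_samp_en",
    "binen_result",
]


@dataclass(frozen=True)
class BinEnConfig:
    """Embedding size ``m``, delay ``tau`` and integer Hamming tolerance ``r``."""

    m: int = 2
    r: int = 2
    tau: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValidationError("m must be >= 1")
        if self.tau < 1:
            raise ValidationError("tau must be >= 1")
        if self.r != int(self.r):
            warnings.warn(
                f"r={self.r} is not an integer; Hamming distances are integers, flooring",
                UserWarning,
            )
            object.__setattr__(self, "r", int(math.floor(self.r)))
        object.__setattr__(self, "r", int(self.r))
        if self.r < 0:
            raise ValidationError("r must be >= 0")


@dataclass(frozen=True)
class BinEnResult:
    """Both entropies plus the order-m intermediates they were built from."""

    config: BinEnConfig
    bin_ap_en: float
    bin_samp_en: float
    phi_m: float
    phi_m1: float
    counts_m: np.ndarray
    pmf_m: np.ndarray


def _as_array(series: TimeSeries | np.ndarray) -> np.ndarray:
    return series.samples if isinstance(series, TimeSeries) else np.asarray(series, dtype=float)


def binarize(series: TimeSeries | np.ndarray) -> np.ndarray:
    """Differential binary code: 1 for a strict increase, 0 otherwise (ties -> 0)."""
    x = _as_array(series)
    if x.size < 2:
        raise ValidationError("binarization needs at least 2 samples")
    return (np.diff(x) > 0).astype(np.uint8)


def window_codes(c: np.ndarray, m: int, tau: int = 1) -> np.ndarray:
    """Decimal codes ``k(i) = sum_n c[i + n*tau] * 2^n`` of all m-bit windows."""
    c = np.asarray(c)
    n_windows = c.size - (m - 1) * tau
    min_len = (m - 1) * tau + 1
    if n_windows < 1:
        raise ValidationError(
            f"code of length {c.size} is too short for m={m}, tau={tau} "
            f"(minimum {min_len})"
        )
    codes = np.zeros(n_windows, dtype=np.int64)
    for n in range(m):
        codes += c[n * tau : n * tau + n_windows].astype(np.int64) << n
    return codes


def vector_histogram(c: np.ndarray, m: int, tau: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Occurrence counts and empirical pmf of the ``2^m`` window symbols."""
    codes = window_codes(c, m, tau)
    counts = np.bincount(codes, minlength=2**m).astype(np.int64)
    return counts, counts / codes.size


def hamming_matrix(m: int) -> np.ndarray:
    """``2^m x 2^m`` matrix of Hamming distances between symbol codes."""
    if not 1 <= m <= 16:
        raise ValidationError("m must be in 1..16")
    ks = np.arange(2**m, dtype=np.uint32)
    return np.bitwise_count(ks[:, None] ^ ks[None, :]).astype(np.int64)


def phi(pmf: np.ndarray, h: np.ndarray, r: int) -> float:
    """``Phi = sum_k pmf(k) * ln(p_hat_k)`` with ``p_hat_k = P(distance <= r)``.

    Symbols with zero probability contribute nothing.  Since every symbol
    is within distance 0 of itself, ``p_hat_k > 0`` wherever ``pmf(k) > 0``
    and the logarithm is always finite; the result is ``<= 0``.
    """
    pmf = np.asarray(pmf, dtype=float)
    near = h <= r
    p_hat = near @ pmf
    support = pmf > 0
    assert np.all(p_hat[support] > 0), "a realized symbol always matches itself"
    return float(np.sum(pmf[support] * np.log(p_hat[support])))


def phi_excluding_self(counts: np.ndarray, h: np.ndarray, r: int) -> float:
    """Self-match-free variant used by BinSampEn.

    For a window of symbol ``k`` the neighbour proportion is
    ``(sum_n counts(n) * [h(k,n) <= r] - 1) / (L - 1)`` — its own
    occurrence removed from numerator and denominator.  A window with no
    other neighbour within ``r`` drives the sum to ``-inf``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total < 2:
        raise ValidationError("need at least 2 windows to exclude self-matches")
    near = h <= r
    neighbour_counts = near @ counts - 1  # remove the self-match
    support = counts > 0
    if np.any(neighbour_counts[support] <= 0):
        return float("-inf")
    weights = counts[support] / total
    p_hat = neighbour_counts[support] / (total - 1)
    return float(np.sum(weights * np.log(p_hat)))


def _check_length(c: np.ndarray, m: int, tau: int) -> None:
    if c.size - m * tau < 1:  # order m+1 windows must exist
        raise ValidationError(
            f"code of length {c.size} is too short for order m+1={m + 1} windows at tau={tau}"
        )


def bin_ap_en(series: TimeSeries | np.ndarray, cfg: BinEnConfig = BinEnConfig()) -> float:
    """Binarized approximate entropy ``Phi^m - Phi^{m+1}``."""
    c = binarize(series)
    _check_length(c, cfg.m, cfg.tau)
    phis = []
    for order in (cfg.m, cfg.m + 1):
        _, pmf = vector_histogram(c, order, cfg.tau)
        phis.append(phi(pmf, hamming_matrix(order), cfg.r))
    return phis[0] - phis[1]


def bin_samp_en(series: TimeSeries | np.ndarray, cfg: BinEnConfig = BinEnConfig()) -> float:
    """Binarized sample entropy ``-10 * log10(Phi~^{m+1} / Phi~^m)``.

    Returns NaN with a warning when undefined (constant input, zero
    ``Phi~^m``, or a non-positive ratio).
    """
    c = binarize(series)
    _check_length(c, cfg.m, cfg.tau)
    phis = []
    for order in (cfg.m, cfg.m + 1):
        counts, _ = vector_histogram(c, order, cfg.tau)
        phis.append(phi_excluding_self(counts, hamming_matrix(order), cfg.r))
    phi_m, phi_m1 = phis
    if phi_m == 0.0 or not np.isfinite(phi_m) or not np.isfinite(phi_m1):
        warnings.warn("BinSampEn undefined: degenerate Phi~ values", UserWarning)
        return float("nan")
    ratio = phi_m1 / phi_m
    if ratio <= 0:
        warnings.warn("BinSampEn undefined: non-positive Phi~ ratio", UserWarning)
        return float("nan")
    return -10.0 * math.log10(ratio)


def binen_result(series: TimeSeries | np.ndarray, cfg: BinEnConfig = BinEnConfig()) -> BinEnResult:
    """Compute both entropies and keep the order-m intermediates."""
    c = binarize(series)
    _check_length(c, cfg.m, cfg.tau)
    counts_m, pmf_m = vector_histogram(c, cfg.m, cfg.tau)
    _, pmf_m1 = vector_histogram(c, cfg.m + 1, cfg.tau)
    phi_m = phi(pmf_m, hamming_matrix(cfg.m), cfg.r)
    phi_m1 = phi(pmf_m1, hamming_matrix(cfg.m + 1), cfg.r)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sampen = bin_samp_en(series, cfg)
    return BinEnResult(
        config=cfg,
        bin_ap_en=phi_m - phi_m1,
        bin_samp_en=sampen,
        phi_m=phi_m,
        phi_m1=phi_m1,
        counts_m=counts_m,
        pmf_m=pmf_m,
    )
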