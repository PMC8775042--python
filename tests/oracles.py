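"""Independent brute-force transcriptions used as test oracles.

Everything here is written directly from the method's defining formulas,
deliberately sharing no code with the package: generic polynomial fitting
via numpy.polyfit, O(n^2) pairwise window comparison for the binarized
entropies, and a straight line-by-line rendition of the reduction
procedure.  Slow and simple on purpose.
"""

from __future__ import annotations

import math

import numpy as np


def fd_oracle(x: np.ndarray, sl: int, mode: str = "forward", form: str = "rms") -> np.ndarray:
    """Per-segment detrended fluctuation, computed the long way."""
    x = np.asarray(x, dtype=float)
    n = x.size
    profile = np.cumsum(x - np.mean(x))
    n_seg = n // sl
    starts = [j * sl for j in range(n_seg)]
    if mode == "bidirectional":
        rem = n - n_seg * sl
        starts = starts + [rem + j * sl for j in range(n_seg)]
    values = []
    for s in starts:
        seg = profile[s : s + sl]
        k = np.arange(1, sl + 1, dtype=float)
        coeffs = np.polyfit(k, seg, 1)  # generic polynomial fit, order 1
        resid = seg - np.polyval(coeffs, k)
        mean_sq = np.sum(resid**2) / sl
        values.append(math.sqrt(mean_sq) if form == "rms" else mean_sq)
    return np.asarray(values)


def th1_oracle(x: np.ndarray, fd: np.ndarray, c: float, c1: float) -> float:
    """Straight-line transcription of the TH1 formula."""
    x = np.asarray(x, dtype=float)
    fd = np.asarray(fd, dtype=float)
    m = np.sum(x**2) / x.size
    half_range = (np.max(x) - np.min(x)) / 2.0
    sd_fd = np.std(fd, ddof=1)
    sd_x = np.std(x, ddof=1)
    return (half_range**2 - m) * c * np.median(fd) + (sd_fd + sd_x) / (sd_fd * sd_x) * c1


def binarize_oracle(x: np.ndarray) -> np.ndarray:
    c = []
    for i in range(len(x) - 1):
        c.append(1 if x[i + 1] - x[i] > 0 else 0)
    return np.asarray(c, dtype=int)


def _windows(c: np.ndarray, m: int, tau: int) -> list[tuple[int, ...]]:
    n_w = len(c) - (m - 1) * tau
    return [tuple(int(c[i + n * tau]) for n in range(m)) for i in range(n_w)]


def _hamming(a: tuple[int, ...], b: tuple[int, ...]) -> int:
    return sum(1 for u, v in zip(a, b) if u != v)


def phi_pairwise(x: np.ndarray, m: int, r: int, tau: int, exclude_self: bool) -> float:
    """Phi by direct pairwise window comparison (the Eq-13 distance form)."""
    c = binarize_oracle(x)
    wins = _windows(c, m, tau)
    n_w = len(wins)
    logs = []
    for i in range(n_w):
        cnt = 0
        for j in range(n_w):
            if exclude_self and i == j:
                continue
            if _hamming(wins[i], wins[j]) <= r:
                cnt += 1
        denom = n_w - 1 if exclude_self else n_w
        prop = cnt / denom
        logs.append(math.log(prop) if prop > 0 else -math.inf)
    return float(np.mean(logs))


def bin_ap_en_pairwise(x: np.ndarray, m: int, r: int, tau: int = 1) -> float:
    return phi_pairwise(x, m, r, tau, False) - phi_pairwise(x, m + 1, r, tau, False)


def bin_samp_en_pairwise(x: np.ndarray, m: int, r: int, tau: int = 1) -> float:
    phi_m = phi_pairwise(x, m, r, tau, True)
    phi_m1 = phi_pairwise(x, m + 1, r, tau, True)
    if phi_m == 0.0 or not math.isfinite(phi_m) or not math.isfinite(phi_m1):
        return float("nan")
    ratio = phi_m1 / phi_m
    if ratio <= 0:
        return float("nan")
    return -10.0 * math.log10(ratio)


def reduction_oracle(
    x: np.ndarray,
    fs: float,
    sl_seconds: float = 0.5,
    c: float = 0.25,
    c1: float = 1.0,
    adjacency: str = "difference",
) -> list[str]:
    """Step-by-step transcription of the reduction procedure.

    Returns the per-segment reasons: kept / coarse / adjacent / slow.
    Forward segmentation for long series, doubled end-aligned segmentation
    for series under 10,000 samples.
    """
    x = np.asarray(x, dtype=float)
    sl = int(round(sl_seconds * fs))
    mode = "bidirectional" if x.size < 10_000 else "forward"
    fd = fd_oracle(x, sl, mode=mode, form="rms")
    n_seg_half = x.size // sl
    blocks = [(0, n_seg_half), (n_seg_half, 2 * n_seg_half)] if mode == "bidirectional" else [
        (0, n_seg_half)
    ]

    m2 = np.sum(x**2) / x.size
    statistic = (np.max(x) - np.min(x)) / 2.0 - math.sqrt(m2)
    th1 = th1_oracle(x, fd, c, c1)
    th2 = th1 / 2.0
    th3 = 0.1

    reasons = ["kept"] * len(fd)
    if statistic > 1.0:
        for j in range(len(fd)):
            if fd[j] > th1:
                reasons[j] = "coarse"
        for lo, hi in blocks:
            for j in range(lo, hi):
                if fd[j] > th1:
                    for nb in (j - 1, j + 1):
                        if nb < lo or nb >= hi or reasons[nb] != "kept":
                            continue
                        if adjacency == "difference":
                            if fd[j] - fd[nb] > th2:
                                reasons[nb] = "adjacent"
                        else:
                            if fd[nb] > th2:
                                reasons[nb] = "adjacent"
    if np.mean(fd) - np.std(fd, ddof=1) > th3:
        for j in range(len(fd)):
            if reasons[j] == "kept" and fd[j] <= th3:
                reasons[j] = "slow"
    return reasons


def snr_oracle(x: np.ndarray, useful: list) -> float:
    """Direct transcription of the useful/useless power-ratio definition."""
    x = np.asarray(x, dtype=float)
    mask = np.zeros(x.size, dtype=bool)
    for iv in useful:
        mask[int(iv[0]) : int(iv[1])] = True
    ps = np.sum(x[mask] ** 2) / mask.sum()
    pn = np.sum(x[~mask] ** 2) / (~mask).sum()
    return 10.0 * math.log10(ps / pn)
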