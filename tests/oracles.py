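"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library calls used by the implementation:
peak detection is enumerated from the definition (local maxima with
plateau midpoints, greedy height-priority distance suppression,
topographic prominence), so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def local_maxima(s: np.ndarray) -> list[int]:
    """Strict local maxima; plateaus resolved to their midpoint."""
    maxima = []
    i = 1
    n = len(s)
    while i < n - 1:
        if s[i - 1] < s[i]:
            j = i
            while j < n - 1 and s[j + 1] == s[j]:
                j += 1
            if j < n - 1 and s[j + 1] < s[i]:
                maxima.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return maxima


def prominence(s: np.ndarray, peak: int) -> float:
    """Topographic prominence of a local maximum.

    Walk outward from the peak on each side until the series exceeds
    the peak height (or the end); the base on that side is the minimum
    over the walk.  Prominence is peak height minus the higher base.
    """
    h = s[peak]
    left_base = h
    for i in range(peak - 1, -1, -1):
        if s[i] > h:
            break
        left_base = min(left_base, s[i])
    right_base = h
    for i in range(peak + 1, len(s)):
        if s[i] > h:
            break
        right_base = min(right_base, s[i])
    return float(h - max(left_base, right_base))


def enumerate_peaks(s, min_prominence: float, min_distance: int) -> list[int]:
    """Reference peak set: maxima -> distance suppression -> prominence.

    Distance suppression is greedy by peak height (higher peaks claim
    their neighbourhood first); the prominence filter runs afterwards on
    the full series.
    """
    s = np.asarray(s, dtype=float)
    maxima = local_maxima(s)
    m = len(maxima)
    keep = [True] * m
    order = np.argsort([s[p] for p in maxima], kind="stable")
    for idx in reversed(order):
        if not keep[idx]:
            continue
        j = idx - 1
        while j >= 0 and maxima[idx] - maxima[j] < min_distance:
            keep[j] = False
            j -= 1
        j = idx + 1
        while j < m and maxima[j] - maxima[idx] < min_distance:
            keep[j] = False
            j += 1
    survivors = [p for p, k in zip(maxima, keep) if k]
    return [p for p in survivors if prominence(s, p) >= min_prominence]


def poincare_pairs(s, lag: int = 1) -> tuple[float, float]:
    """Poincaré SD1/SD2 by explicit pair enumeration (population std)."""
    s = np.asarray(s, dtype=float)
    diffs = [s[t + lag] - s[t] for t in range(len(s) - lag)]
    sums = [s[t + lag] + s[t] for t in range(len(s) - lag)]

    def pstd(v):
        m = sum(v) / len(v)
        return (sum((x - m) ** 2 for x in v) / len(v)) ** 0.5

    return pstd(diffs) / 2 ** 0.5, pstd(sums) / 2 ** 0.5
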