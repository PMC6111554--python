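"""Independent brute-force reference implementations used only by tests.

These deliberately take the most literal computational route (walk-outs,
template matching, direct DFT sums) so they share no code path with the
package implementations they check.
"""

import numpy as np


def local_maxima(x: np.ndarray) -> list[int]:
    """Indices of strict/plateau-left local maxima by exhaustive scan."""
    x = np.asarray(x, dtype=float)
    out = []
    i = 1
    while i < len(x) - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < len(x) - 1 and x[j + 1] == x[i]:
                j += 1
            if j < len(x) - 1 and x[j + 1] < x[i]:
                out.append(i)  # leftmost sample of the (possibly flat) top
            i = j + 1
        else:
            i += 1
    return out


def prominence_walkout(x: np.ndarray, i: int) -> float:
    """Topographic prominence by literal left/right walk-out."""
    x = np.asarray(x, dtype=float)
    height = x[i]
    valleys = []
    for step in (-1, 1):
        lowest = height
        j = i + step
        while 0 <= j < len(x) and x[j] <= height:
            lowest = min(lowest, x[j])
            j += step
        valleys.append(lowest)
    return height - max(valleys)


def count_prominent_peaks(x: np.ndarray, min_prominence: float) -> int:
    return sum(
        prominence_walkout(x, i) >= min_prominence for i in local_maxima(x)
    )


def sample_entropy_naive(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """O(n^2) template matching straight from the definition."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = r_frac * x.std()

    def count(mm: int) -> int:
        c = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if np.max(np.abs(x[i : i + mm] - x[j : j + mm])) <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if b == 0 or a == 0:
        return np.nan
    return -np.log(a / b)


def dft_coefficient(x: np.ndarray, k: int) -> complex:
    """k-th DFT coefficient from the definition sum."""
    n = len(x)
    idx = np.arange(n)
    return complex(np.sum(x * np.exp(-2j * np.pi * k * idx / n)))


def ratio_beyond_sigma_naive(x: np.ndarray, r: float) -> float:
    x = np.asarray(x, dtype=float)
    mu, sd = np.mean(x), np.std(x)
    return sum(1 for v in x if abs(v - mu) > r * sd) / len(x)
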