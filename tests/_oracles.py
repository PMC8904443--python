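"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the definitions — direct
summation, explicit loops, sorting — and stays independent of the package's
FFT/vectorized code paths it is used to check.
"""

from __future__ import annotations

import math

import numpy as np


def direct_dft(x: np.ndarray) -> np.ndarray:
    """O(T^2) direct-summation DFT, bin k holds sum_t x_t exp(-2i pi k t / T)."""
    x = np.asarray(x, dtype=complex)
    t = x.size
    n = np.arange(t)
    return np.array([np.sum(x * np.exp(-2j * np.pi * k * n / t)) for k in range(t)])


def direct_highpass(x: np.ndarray, dt: float, cutoff: float) -> np.ndarray:
    """Brick-wall high-pass realized with the direct DFT and its inverse."""
    t = x.size
    spec = direct_dft(x)
    freqs = np.fft.fftfreq(t, d=dt)
    spec[np.abs(freqs) < cutoff] = 0.0
    n = np.arange(t)
    return np.array(
        [np.sum(spec * np.exp(2j * np.pi * k * n / t)) / t for k in range(t)]
    )


def direct_periodicity(x: np.ndarray, dt: float, cutoff: float, band: tuple[float, float]) -> float:
    """Spectral periodicity from scratch: direct DFT, brick-wall mask, band peak.

    Numerator: root sum square of the ±cardiac-frequency bins; denominator:
    root sum square over every retained bin.
    """
    t = x.size
    spec = direct_dft(x)
    freqs = np.fft.fftfreq(t, d=dt)
    spec[np.abs(freqs) < cutoff] = 0.0
    lo, hi = band
    best_k, best_p = None, -1.0
    for k in range(1, t):
        f = freqs[k]
        if f <= 0 or not (lo <= f <= hi):
            continue
        p = abs(spec[k]) ** 2 + abs(spec[(t - k) % t]) ** 2
        if p > best_p + 1e-300 and p > best_p:
            best_k, best_p = k, p
    num = abs(spec[best_k]) ** 2 + abs(spec[(t - best_k) % t]) ** 2
    den = sum(abs(s) ** 2 for s in spec)
    return math.sqrt(num) / math.sqrt(den)


def loop_pearson(x: np.ndarray, y: np.ndarray) -> complex:
    """Complex Pearson coefficient from the definition, scalar loops only."""
    t = len(x)
    mx = sum(x) / t
    my = sum(y) / t
    num = sum((xi - mx) * np.conj(yi - my) for xi, yi in zip(x, y))
    vx = sum(abs(xi - mx) ** 2 for xi in x)
    vy = sum(abs(yi - my) ** 2 for yi in y)
    return num / math.sqrt(vx * vy)


def loop_correlation_map(frames: np.ndarray, ref: np.ndarray, va: np.ndarray) -> np.ndarray:
    """Per-voxel |Pearson| against ref via an explicit voxel loop (no filtering)."""
    out = np.full(va.shape, np.nan)
    for i in range(va.shape[0]):
        for j in range(va.shape[1]):
            if not va[i, j]:
                continue
            series = frames[:, i, j]
            if np.allclose(series, series[0]):
                out[i, j] = 0.0
            else:
                out[i, j] = abs(loop_pearson(series, ref))
    return out


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch statistic and degrees of freedom from the textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    va = a.var(ddof=1) / na
    vb = b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return t, df


def welch_one_tailed_p(a: np.ndarray, b: np.ndarray, direction: str) -> tuple[float, float]:
    """One-tailed Welch p from the t CDF (scipy's distribution, not its test)."""
    from scipy.stats import t as t_dist

    t, df = welch_t(a, b)
    if direction == "greater":
        p = t_dist.sf(t, df)
    else:
        p = t_dist.cdf(t, df)
    return t, p


def sorted_quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """25/50/75th percentiles by sorting and linear interpolation, by hand."""
    x = sorted(float(v) for v in values)
    n = len(x)

    def pct(q: float) -> float:
        pos = q * (n - 1)
        lo = math.floor(pos)
        hi = math.ceil(pos)
        if lo == hi:
            return x[lo]
        w = pos - lo
        return x[lo] * (1 - w) + x[hi] * w

    return pct(0.25), pct(0.5), pct(0.75)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Real Pearson R from the definition."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2)))


def rasterized_disk_count(rows: int, cols: int, ci: float, cj: float, r: float) -> int:
    """Count pixels with center distance <= r by exhaustive enumeration."""
    count = 0
    for i in range(rows):
        for j in range(cols):
            if math.hypot(i - ci, j - cj) <= r:
                count += 1
    return count
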