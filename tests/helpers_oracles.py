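"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths (and scipy's peak utilities)
so that agreement with them is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def brute_force_peaks(
    x: np.ndarray, threshold: float, prominence: float
) -> list[tuple[int, float, float]]:
    """Exhaustive local-maximum + topographic-prominence scan.

    Every sample is tested as a local maximum (strictly higher than the
    nearest non-equal neighbour on each side; plateaus resolved to their
    earliest index; boundary samples can never be peaks).  Prominence is
    found by walking outward to higher ground on each side and taking the
    peak height minus the higher of the two intervening minima.  Returns
    (index, height, prominence) for peaks clearing both thresholds.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    candidates = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if x[i - 1] < x[i] and j + 1 < n and x[j + 1] < x[i]:
            candidates.append(i)
        i = j + 1

    out = []
    for p in candidates:
        h = x[p]
        left_min = h
        k = p - 1
        while k >= 0 and x[k] <= h:
            left_min = min(left_min, x[k])
            k -= 1
        right_min = h
        k = p + 1
        while k < n and x[k] <= h:
            right_min = min(right_min, x[k])
            k += 1
        prom = h - max(left_min, right_min)
        if h >= threshold and prom >= prominence:
            out.append((p, float(h), float(prom)))
    return out


def percentile_sorted(values: np.ndarray, q: float) -> float:
    """Percentile by explicit sort and linear interpolation between order
    statistics (independent of numpy.percentile)."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = (v.size - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def counting_cumulative_length(
    profile: np.ndarray, pixel_len: float, levels: np.ndarray
) -> np.ndarray:
    """Per-level pixel counting by explicit loops."""
    out = np.empty(len(levels))
    for i, f in enumerate(levels):
        c = 0
        for v in profile:
            if v >= f:
                c += 1
        out[i] = pixel_len * c
    return out


def moving_mean_direct(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving mean with shrinking edge windows, by explicit slicing."""
    n = len(x)
    half = window // 2
    return np.array(
        [np.mean(x[max(0, i - half): min(n, i + half + 1)]) for i in range(n)]
    )


def pearson_direct(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r from the raw covariance formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def anova_f_direct(groups: list[np.ndarray]) -> tuple[float, int, int]:
    """One-way ANOVA F from the textbook sums-of-squares decomposition."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = allv.size - len(groups)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


def permutation_p_oneway(
    groups: list[np.ndarray], n_perm: int, rng: np.random.Generator
) -> float:
    """Permutation p-value for the one-way ANOVA F statistic."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    f_obs, _, _ = anova_f_direct(groups)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        splits = np.split(perm, np.cumsum(sizes)[:-1])
        f, _, _ = anova_f_direct(splits)
        if f >= f_obs:
            count += 1
    return (count + 1) / (n_perm + 1)
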