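"""Independent brute-force oracles used by unit and acceptance tests.

Deliberately naive implementations (queue-based flood fill, per-pixel
scoring, explicit ANOVA arithmetic) kept free of the package's own code
paths so they can arbitrate them.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill(in_band: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """Queue-based 8-connected flood fill of a boolean field from a seed."""
    h, w = in_band.shape
    mask = np.zeros_like(in_band, dtype=bool)
    if not in_band[seed]:
        return mask
    queue = deque([seed])
    mask[seed] = True
    while queue:
        r, c = queue.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and in_band[rr, cc] and not mask[rr, cc]:
                    mask[rr, cc] = True
                    queue.append((rr, cc))
    return mask


def flood_fill_4(in_band: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """4-connected variant, for lesion grouping."""
    h, w = in_band.shape
    mask = np.zeros_like(in_band, dtype=bool)
    if not in_band[seed]:
        return mask
    queue = deque([seed])
    mask[seed] = True
    while queue:
        r, c = queue.popleft()
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < h and 0 <= cc < w and in_band[rr, cc] and not mask[rr, cc]:
                mask[rr, cc] = True
                queue.append((rr, cc))
    return mask


def agatston_slice(slice_hu: np.ndarray, pixel_area_mm2: float) -> float:
    """Per-pixel calcium scoring of one slice by exhaustive flood fill."""
    thresholded = slice_hu >= 130.0
    visited = np.zeros_like(thresholded, dtype=bool)
    total = 0.0
    for r in range(slice_hu.shape[0]):
        for c in range(slice_hu.shape[1]):
            if thresholded[r, c] and not visited[r, c]:
                lesion = flood_fill_4(thresholded, (r, c))
                visited |= lesion
                area = lesion.sum() * pixel_area_mm2
                if area < 1.0:
                    continue
                peak = slice_hu[lesion].max()
                if peak >= 400:
                    weight = 4
                elif peak >= 300:
                    weight = 3
                elif peak >= 200:
                    weight = 2
                else:
                    weight = 1
                total += area * weight
    return total


def average_ranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing the mean rank."""
    values = np.asarray(values, dtype=np.float64)
    ranks = np.empty(values.size)
    order = np.argsort(values, kind="stable")
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of average ranks."""
    rx, ry = average_ranks(x), average_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def icc21(table: np.ndarray) -> float:
    """ICC(2,1) from an explicitly assembled two-way ANOVA table."""
    t = np.asarray(table, dtype=np.float64)
    n, k = t.shape
    grand = t.mean()
    msr = k * ((t.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((t.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((t - grand) ** 2).sum() - k * ((t.mean(axis=1) - grand) ** 2).sum() - n * (
        (t.mean(axis=0) - grand) ** 2
    ).sum()
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))
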