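"""Independent brute-force oracles used to cross-check the pipeline.

Each oracle computes the same quantity as a pipeline operation by the most
direct method available (exhaustive search, per-pixel windows, flood fill,
enumeration of all assignments), deliberately sharing no code with the
implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


def otsu_exhaustive(img: np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold by trying all split points of a [min, max] histogram.

    For every candidate split k, pixels in bins 0..k form class 0 and the
    rest class 1; the split maximizing w0*w1*(mu0-mu1)^2 wins, lowest k on
    ties.  Returns the upper edge of bin k.
    """
    lo, hi = float(img.min()), float(img.max())
    counts, edges = np.histogram(img, bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    scores: list[tuple[int, float]] = []
    for k in range(n_bins - 1):
        w0 = counts[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / w1
        scores.append((k, w0 * w1 * (mu0 - mu1) ** 2))
    vmax = max(v for _, v in scores)
    # ties (exact up to floating-point round-off) go to the lowest bin
    best_k = next(k for k, v in scores if v >= vmax * (1.0 - 1e-12))
    return float(edges[best_k + 1])


def window_median(img: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel sorted-window median with nearest-edge replication."""
    h, w = img.shape
    out = np.empty_like(img, dtype=np.float64)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    vals.append(img[yy, xx])
            out[y, x] = float(np.median(vals))
    return out


def window_variance(img: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel population variance of the window, nearest replication."""
    h, w = img.shape
    out = np.empty((h, w), dtype=np.float64)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    vals.append(float(img[yy, xx]))
            m = sum(vals) / len(vals)
            out[y, x] = sum((v - m) ** 2 for v in vals) / len(vals)
    return out


def _neighbors(ndim: int, full: bool):
    offsets = []
    for off in itertools.product((-1, 0, 1), repeat=ndim):
        if all(o == 0 for o in off):
            continue
        if not full and sum(abs(o) for o in off) != 1:
            continue
        offsets.append(off)
    return offsets


def flood_fill_label(mask: np.ndarray, full_connectivity: bool) -> np.ndarray:
    """Connected components by BFS flood fill, raster-ordered labels."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    offsets = _neighbors(mask.ndim, full_connectivity)
    next_label = 0
    for idx in np.ndindex(mask.shape):
        if mask[idx] and labels[idx] == 0:
            next_label += 1
            queue = deque([idx])
            labels[idx] = next_label
            while queue:
                cur = queue.popleft()
                for off in offsets:
                    nb = tuple(c + o for c, o in zip(cur, off))
                    if all(0 <= c < s for c, s in zip(nb, mask.shape)):
                        if mask[nb] and labels[nb] == 0:
                            labels[nb] = next_label
                            queue.append(nb)
    return labels


def brute_force_assignment(
    a: np.ndarray,
    b: np.ndarray,
    max_dist_um: float,
    preferred_deg: float,
    max_dev_deg: float,
    pixel_size: float,
) -> tuple[int, float]:
    """Best one-to-one linking by enumerating all injective mappings.

    Maximizes the number of admissible links, then minimizes total physical
    distance.  Returns (n_links, total_distance_um).
    """

    def ok(p, q):
        d = q - p
        dist = math.hypot(*d) * pixel_size
        if dist > max_dist_um:
            return None
        if d[0] == 0 and d[1] == 0:
            return dist
        ang = math.degrees(math.atan2(d[1], d[0]))
        diff = abs((ang - preferred_deg + 180.0) % 360.0 - 180.0)
        return dist if diff <= max_dev_deg else None

    n, m = len(a), len(b)
    best = (0, 0.0)
    k = min(n, m)
    indices_a = list(range(n))
    for subset in itertools.combinations(indices_a, k) if n > m else [tuple(indices_a)]:
        for perm in itertools.permutations(range(m), k):
            count, total = 0, 0.0
            for i, j in zip(subset, perm):
                d = ok(a[i], b[j])
                if d is not None:
                    count += 1
                    total += d
            if count > best[0] or (count == best[0] and (count == 0 or total < best[1])):
                best = (count, total)
    return best
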