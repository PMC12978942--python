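"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately naive (flood fill, sequential rejection,
O(n^3) agglomeration, direct formula evaluation) and shares no code with
the package paths it validates.
"""

from __future__ import annotations

import itertools

import numpy as np


def flood_fill_components(mask: np.ndarray) -> list[frozenset]:
    """8-connected components of a boolean mask via explicit flood fill."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or visited[sy, sx]:
                continue
            stack = [(sy, sx)]
            visited[sy, sx] = True
            comp = set()
            while stack:
                y, x = stack.pop()
                comp.add((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not visited[ny, nx]:
                            visited[ny, nx] = True
                            stack.append((ny, nx))
            comps.append(frozenset(comp))
    return comps


def area_filtered_partition(mask: np.ndarray, a_min: float, a_max: float) -> set[frozenset]:
    """Label partition of the 8-connected components with area in [a_min, a_max]."""
    return {c for c in flood_fill_components(mask) if a_min <= len(c) <= a_max}


def holm_sequential(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down procedure by literal sequential rejection."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject


def upgma_heights(points: np.ndarray) -> list[float]:
    """Merge heights of average-linkage clustering, O(n^3) from first principles.

    Inter-cluster distance is the mean of all pairwise point distances;
    ties break on the lowest member indices for determinism.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = float(np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]]))
            key = (d, tuple(sorted(clusters[a])), tuple(sorted(clusters[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return heights


def random_blob_mask(rng: np.random.Generator, max_side: int = 64) -> np.ndarray:
    """A random binary mask mixing sparse noise with a few dilated blobs."""
    h = int(rng.integers(4, max_side + 1))
    w = int(rng.integers(4, max_side + 1))
    mask = rng.random((h, w)) < rng.uniform(0.05, 0.45)
    for _ in range(int(rng.integers(0, 4))):
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        r = int(rng.integers(1, 6))
        yy, xx = np.mgrid[:h, :w]
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask
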