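"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written the slow, obvious way (explicit loops, BFS,
exhaustive search) and shares no code path with the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def brute_grey_close(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Grayscale closing via explicit max-then-min filters.

    Out-of-bounds neighbours are simply excluded from each window (the
    finite-domain rule)."""

    offs = [
        (dy - footprint.shape[0] // 2, dx - footprint.shape[1] // 2)
        for dy in range(footprint.shape[0])
        for dx in range(footprint.shape[1])
        if footprint[dy, dx]
    ]
    h, w = img.shape

    def _filter(arr, agg):
        out = np.empty_like(arr)
        for y in range(h):
            for x in range(w):
                vals = [
                    arr[y + dy, x + dx]
                    for dy, dx in offs
                    if 0 <= y + dy < h and 0 <= x + dx < w
                ]
                out[y, x] = agg(vals)
        return out

    return _filter(_filter(img, max), min)


def flood_fill_label(mask: np.ndarray, connectivity: int = 8):
    """BFS connected-component labelling; labels assigned in raster order."""
    if connectivity == 4:
        nbrs = ((-1, 0), (1, 0), (0, -1), (0, 1))
    else:
        nbrs = tuple(
            (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)
        )
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    cur = 0
    for y in range(h):
        for x in range(w):
            if mask[y, x] and labels[y, x] == 0:
                cur += 1
                q = deque([(y, x)])
                labels[y, x] = cur
                while q:
                    cy, cx = q.popleft()
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if (
                            0 <= ny < h
                            and 0 <= nx < w
                            and mask[ny, nx]
                            and labels[ny, nx] == 0
                        ):
                            labels[ny, nx] = cur
                            q.append((ny, nx))
    return labels, cur


def largest_component_oracle(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    labels, n = flood_fill_label(mask, connectivity)
    if n == 0:
        return np.zeros_like(mask)
    sizes = [(labels == i).sum() for i in range(1, n + 1)]
    best = int(np.argmax(sizes)) + 1  # first max = raster-order tie-break
    return labels == best


def hole_count_oracle(mask: np.ndarray) -> int:
    """Background pixels unreachable from the border by 4-connected BFS."""
    h, w = mask.shape
    reach = np.zeros((h, w), dtype=bool)
    q = deque()
    for y in range(h):
        for x in (0, w - 1):
            if not mask[y, x] and not reach[y, x]:
                reach[y, x] = True
                q.append((y, x))
    for x in range(w):
        for y in (0, h - 1):
            if not mask[y, x] and not reach[y, x]:
                reach[y, x] = True
                q.append((y, x))
    while q:
        cy, cx = q.popleft()
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ny, nx = cy + dy, cx + dx
            if 0 <= ny < h and 0 <= nx < w and not mask[ny, nx] and not reach[ny, nx]:
                reach[ny, nx] = True
                q.append((ny, nx))
    return int((~mask & ~reach).sum())


def feret_oracle(mask: np.ndarray) -> float:
    """Max pairwise distance over ALL boundary pixels, O(n^2)."""
    h, w = mask.shape
    boundary = []
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                edge = False
                for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < h and 0 <= nx < w) or not mask[ny, nx]:
                        edge = True
                if edge:
                    boundary.append((y, x))
    best = 0.0
    for i in range(len(boundary)):
        for j in range(i + 1, len(boundary)):
            dy = boundary[i][0] - boundary[j][0]
            dx = boundary[i][1] - boundary[j][1]
            best = max(best, dy * dy + dx * dx)
    return float(np.sqrt(best))


def knn_predict_oracle(train: np.ndarray, labels: np.ndarray, x: np.ndarray,
                       k: int) -> int:
    """Exhaustive KNN: sort every (distance, index) pair, majority vote,
    even ties resolved by the single nearest neighbour."""
    dists = [
        (float(np.sqrt(((train[i] - x) ** 2).sum())), i)
        for i in range(len(train))
    ]
    dists.sort()
    chosen = [i for _, i in dists[:k]]
    ones = sum(int(labels[i]) for i in chosen)
    zeros = k - ones
    if ones > zeros:
        return 1
    if zeros > ones:
        return 0
    return int(labels[chosen[0]])


def loo_select_k_oracle(features: np.ndarray, labels: np.ndarray, k_grid):
    """Independent leave-one-out grid search with z-scored features."""
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (features - mu) / sd
    n = len(z)
    best_k, best_acc = None, -1.0
    curve = []
    for k in sorted(k_grid):
        correct = 0
        for i in range(n):
            keep = [j for j in range(n) if j != i]
            pred = knn_predict_oracle(z[keep], labels[keep], z[i], k)
            correct += pred == labels[i]
        acc = correct / n
        curve.append((k, acc))
        if acc > best_acc:
            best_k, best_acc = k, acc
    return best_k, curve


def digital_disk(radius: int, size: int | None = None) -> np.ndarray:
    """Exact rasterization of a disk: x^2 + y^2 <= r^2."""
    if size is None:
        size = 2 * radius + 5
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius * radius


def random_blob(rng: np.random.Generator, size: int = 40) -> np.ndarray:
    """Union of random disks all overlapping a central one: single blob."""
    mask = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    c = size // 2
    r0 = rng.integers(5, size // 4)
    mask |= (yy - c) ** 2 + (xx - c) ** 2 <= r0 * r0
    for _ in range(rng.integers(1, 5)):
        cy = c + rng.integers(-r0, r0 + 1)
        cx = c + rng.integers(-r0, r0 + 1)
        r = rng.integers(3, r0 + 3)
        add = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        mask |= add
    return mask
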