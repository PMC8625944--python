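"""Independent brute-force oracles used by the test suite.

Everything here is written naively (loops, exhaustive search, linear
scans) and shares no code with the package implementation, so agreement
between the two is evidence, not tautology.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
OFFSETS4 = ((-1, 0), (0, -1), (0, 1), (1, 0))


def median_filter(img: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel sorted-neighborhood median with replicate padding."""
    h, w = img.shape
    r = window // 2
    out = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            vals = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    y = min(max(i + di, 0), h - 1)
                    x = min(max(j + dj, 0), w - 1)
                    vals.append(img[y, x])
            vals.sort()
            out[i, j] = vals[len(vals) // 2]
    return out


def otsu_threshold(img: np.ndarray) -> int:
    """Exhaustive argmax of the between-class variance over all levels."""
    flat = [int(v) for v in img.ravel()]
    n = len(flat)
    hist = [0] * 256
    for v in flat:
        hist[v] += 1
    mG = sum(i * c for i, c in enumerate(hist)) / n
    best, ties = -1.0, []
    P1 = 0.0
    m = 0.0
    for k in range(256):
        P1 += hist[k] / n
        m += k * hist[k] / n
        if P1 <= 0.0 or P1 >= 1.0:
            continue
        sigma = (mG * P1 - m) ** 2 / (P1 * (1.0 - P1))
        if sigma > best + 1e-12:
            best, ties = sigma, [k]
        elif abs(sigma - best) <= 1e-12:
            ties.append(k)
    return int(sum(ties) / len(ties))


def global_equalize(img: np.ndarray) -> np.ndarray:
    """round(255 * CDF) mapping computed with plain loops."""
    hist = [0] * 256
    for v in img.ravel():
        hist[int(v)] += 1
    n = img.size
    cdf, acc = [], 0
    for c in hist:
        acc += c
        cdf.append(acc / n)
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = int(round(255 * cdf[int(img[i, j])]))
    return out


def edt(mask: np.ndarray) -> np.ndarray:
    """Min-over-all-zero-pixels Euclidean distance."""
    h, w = mask.shape
    zeros = [(i, j) for i in range(h) for j in range(w) if not mask[i, j]]
    out = np.zeros((h, w), dtype=float)
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                out[i, j] = min(
                    math.hypot(i - zi, j - zj) for zi, zj in zeros
                )
    return out


def components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """BFS connected-component labeling, numbered in raster order."""
    offs = OFFSETS8 if connectivity == 8 else OFFSETS4
    h, w = mask.shape
    lab = np.zeros((h, w), dtype=int)
    nxt = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and lab[i, j] == 0:
                nxt += 1
                stack = [(i, j)]
                lab[i, j] = nxt
                while stack:
                    y, x = stack.pop()
                    for dy, dx in offs:
                        q, s = y + dy, x + dx
                        if 0 <= q < h and 0 <= s < w and mask[q, s] and lab[q, s] == 0:
                            lab[q, s] = nxt
                            stack.append((q, s))
    return lab


def area_open(mask: np.ndarray, min_area: int, connectivity: int = 8) -> np.ndarray:
    lab = components(mask, connectivity)
    out = np.zeros_like(mask, dtype=bool)
    for v in range(1, lab.max() + 1):
        comp = lab == v
        if comp.sum() >= min_area:
            out |= comp
    return out


def regional_minima(surface: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Plateau flood: a minimum is a plateau with all neighbors higher."""
    offs = OFFSETS8 if connectivity == 8 else OFFSETS4
    h, w = surface.shape
    out = np.zeros((h, w), dtype=bool)
    visited = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            if visited[i, j]:
                continue
            level = surface[i, j]
            plateau = [(i, j)]
            visited[i, j] = True
            is_min = True
            idx = 0
            while idx < len(plateau):
                y, x = plateau[idx]
                idx += 1
                for dy, dx in offs:
                    q, s = y + dy, x + dx
                    if not (0 <= q < h and 0 <= s < w):
                        continue
                    if surface[q, s] == level:
                        if not visited[q, s]:
                            visited[q, s] = True
                            plateau.append((q, s))
                    elif surface[q, s] < level:
                        is_min = False
            if is_min:
                for y, x in plateau:
                    out[y, x] = True
    return out


def reconstruct_by_erosion(seed: np.ndarray, mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Iterated max(erode(f), mask) to stability; erosion ignores borders."""
    offs = (OFFSETS8 if connectivity == 8 else OFFSETS4) + ((0, 0),)
    f = seed.astype(float).copy()
    g = mask.astype(float)
    h, w = f.shape
    while True:
        prev = f.copy()
        for i in range(h):
            for j in range(w):
                lo = min(
                    prev[i + dy, j + dx]
                    for dy, dx in offs
                    if 0 <= i + dy < h and 0 <= j + dx < w
                )
                f[i, j] = max(lo, g[i, j])
        if np.array_equal(f, prev):
            return f


def h_minima_markers(surface: np.ndarray, h: float, connectivity: int = 8) -> np.ndarray:
    filled = reconstruct_by_erosion(surface + h, surface, connectivity)
    minima = regional_minima(filled, connectivity)
    if minima.all():  # flattened: nothing deeper than h
        return np.zeros_like(minima)
    return minima


def priority_flood(
    surface: np.ndarray,
    connectivity: int = 8,
    markers: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Naive priority flood: linear-scan queue keyed by (height, seq).

    Same flooding semantics as the package contract — ascending height,
    FIFO within a level, raster-order seeding, fixed neighbor scan order,
    ridge where two basins meet — realized with a plain list instead of a
    heap and with its own BFS seed labeling.
    """
    offs = OFFSETS8 if connectivity == 8 else OFFSETS4
    h, w = surface.shape
    domain = np.ones((h, w), bool) if mask is None else mask.astype(bool)
    if markers is None:
        seeds = regional_minima(surface, connectivity) & domain
    else:
        seeds = markers.astype(bool) & domain
    lab = components(seeds, connectivity)
    if lab.max() == 0:
        return np.zeros((h, w), dtype=int)

    queue: list[tuple[float, int, int, int]] = []
    seq = 0
    for i in range(h):
        for j in range(w):
            if seeds[i, j]:
                for dy, dx in offs:
                    q, s = i + dy, j + dx
                    if 0 <= q < h and 0 <= s < w and domain[q, s] and lab[q, s] == 0:
                        queue.append((float(surface[q, s]), seq, q, s))
                        seq += 1
    RIDGE = -1
    while queue:
        best = min(range(len(queue)), key=lambda t: (queue[t][0], queue[t][1]))
        _, _, y, x = queue.pop(best)
        if lab[y, x] != 0:
            continue
        neigh = set()
        for dy, dx in offs:
            q, s = y + dy, x + dx
            if 0 <= q < h and 0 <= s < w and lab[q, s] > 0:
                neigh.add(lab[q, s])
        if len(neigh) > 1:
            lab[y, x] = RIDGE
            continue
        if not neigh:
            continue
        lab[y, x] = neigh.pop()
        for dy, dx in offs:
            q, s = y + dy, x + dx
            if 0 <= q < h and 0 <= s < w and domain[q, s] and lab[q, s] == 0:
                queue.append((float(surface[q, s]), seq, q, s))
                seq += 1
    lab[lab == RIDGE] = 0
    return lab


def convex_hull_monotone(points: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Andrew's monotone chain; returns hull vertices counter-clockwise."""
    pts = sorted(set(points))
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def polygon_area(verts: list[tuple[float, float]]) -> float:
    n = len(verts)
    acc = 0.0
    for i in range(n):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % n]
        acc += x0 * y1 - x1 * y0
    return abs(acc) / 2.0
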