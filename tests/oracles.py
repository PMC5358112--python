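"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where feasible, the
libraries) used by the implementation: geodesic reconstruction is
iterated to a fixpoint, the assignment optimum is found by enumerating
permutations, and the watershed flood picks its next pixel by a linear
scan of the frontier instead of a heap.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def hminima_by_iteration(relief: np.ndarray, h: float) -> np.ndarray:
    """h-minima via the defining fixpoint: g <- max(relief, erosion_4(g))
    starting from relief + h, iterated until stable."""
    relief = np.asarray(relief, dtype=np.float64)
    g = relief + h
    while True:
        padded = np.pad(g, 1, mode="constant", constant_values=np.inf)
        eroded = np.minimum.reduce(
            [
                padded[1:-1, 1:-1],
                padded[:-2, 1:-1],
                padded[2:, 1:-1],
                padded[1:-1, :-2],
                padded[1:-1, 2:],
            ]
        )
        nxt = np.maximum(relief, eroded)
        if np.array_equal(nxt, g):
            return g
        g = nxt


def assignment_by_enumeration(cost: np.ndarray) -> float:
    """Minimum total cost of a square assignment, by trying all n! perms."""
    cost = np.asarray(cost, dtype=np.float64)
    n = cost.shape[0]
    perms = np.array(list(permutations(range(n))))
    totals = cost[np.arange(n)[None, :], perms].sum(axis=1)
    return float(totals.min())


def watershed_by_linear_scan(relief: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Marker flood that selects the next pixel by scanning a frontier
    list for the minimal (relief value, insertion order) key.

    Seeds are enqueued by (label, raster index) and neighbours appended
    in raster order, mirroring the declared flooding order.
    """
    relief = np.asarray(relief, dtype=np.float64)
    h, w = relief.shape
    out = markers.astype(np.int64).copy()

    def neighbours(y: int, x: int):
        if y > 0:
            yield y - 1, x
        if x > 0:
            yield y, x - 1
        if x < w - 1:
            yield y, x + 1
        if y < h - 1:
            yield y + 1, x

    frontier: list[tuple[float, int, int]] = []  # (value, label, raster idx)
    seeds = sorted(
        ((int(out[y, x]), y, x) for y in range(h) for x in range(w) if out[y, x] > 0)
    )
    for label, y, x in seeds:
        for ny, nx in neighbours(y, x):
            if out[ny, nx] == 0:
                frontier.append((float(relief[ny, nx]), label, ny * w + nx))
    while frontier:
        # minimal value, earliest insertion (list order preserves age)
        best_pos = min(range(len(frontier)), key=lambda i: frontier[i][0])
        value, label, idx = frontier.pop(best_pos)
        y, x = divmod(idx, w)
        if out[y, x] != 0:
            continue
        out[y, x] = label
        for ny, nx in neighbours(y, x):
            if out[ny, nx] == 0:
                frontier.append((float(relief[ny, nx]), label, ny * w + nx))
    return out


def regional_minima_by_flood(relief: np.ndarray) -> np.ndarray:
    """Boolean regional-minima mask from the definition: a plateau
    (4-connected component of equal value) is a regional minimum iff no
    pixel just outside it is strictly lower."""
    relief = np.asarray(relief, dtype=np.float64)
    h, w = relief.shape
    seen = np.zeros((h, w), dtype=bool)
    out = np.zeros((h, w), dtype=bool)
    for y0 in range(h):
        for x0 in range(w):
            if seen[y0, x0]:
                continue
            val = relief[y0, x0]
            plateau = [(y0, x0)]
            seen[y0, x0] = True
            is_min = True
            i = 0
            while i < len(plateau):
                y, x = plateau[i]
                i += 1
                for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
                    if not (0 <= ny < h and 0 <= nx < w):
                        continue
                    if relief[ny, nx] == val:
                        if not seen[ny, nx]:
                            seen[ny, nx] = True
                            plateau.append((ny, nx))
                    elif relief[ny, nx] < val:
                        is_min = False
            if is_min:
                for y, x in plateau:
                    out[y, x] = True
    return out
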