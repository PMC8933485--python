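"""Independent brute-force oracles used across the suite.

These deliberately re-derive texture matrices by exhaustive enumeration
(pure-python loops, BFS flood fill) rather than reusing any package code
path, so agreement is a genuine two-route check.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def matrix_to_dict(matrix: np.ndarray) -> dict[tuple[int, int], float]:
    """Nonzero entries of a (level, size)-style count matrix, 1-based."""
    out = {}
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            if matrix[i, j] != 0:
                out[(i + 1, j + 1)] = float(matrix[i, j])
    return out


def _in(shape, p):
    return all(0 <= p[a] < shape[a] for a in range(3))


def _neighbors26(distance=1):
    return [
        off
        for off in itertools.product((-distance, 0, distance), repeat=3)
        if off != (0, 0, 0)
    ]


def brute_glcm(levels: np.ndarray, mask: np.ndarray, distance: int = 1) -> dict:
    """Symmetric aggregated co-occurrence counts via enumeration of all 26
    ordered offsets (equivalent to 13 directions symmetrised)."""
    counts: dict[tuple[int, int], float] = {}
    shape = levels.shape
    for p in zip(*np.nonzero(mask)):
        for off in _neighbors26(distance):
            q = tuple(p[a] + off[a] for a in range(3))
            if _in(shape, q) and mask[q]:
                key = (int(levels[p]), int(levels[q]))
                counts[key] = counts.get(key, 0) + 1
    return counts


def brute_glrlm(levels: np.ndarray, mask: np.ndarray) -> dict:
    """Run-length counts over the 13 unique directions by walking runs."""
    shape = levels.shape
    directions = [
        off for off in itertools.product((1, 0, -1), repeat=3) if off > (0, 0, 0)
    ]
    counts: dict[tuple[int, int], float] = {}
    for off in directions:
        for p in zip(*np.nonzero(mask)):
            prev = tuple(p[a] - off[a] for a in range(3))
            if _in(shape, prev) and mask[prev] and levels[prev] == levels[p]:
                continue  # not a run start
            length = 0
            q = p
            while _in(shape, q) and mask[q] and levels[q] == levels[p]:
                length += 1
                q = tuple(q[a] + off[a] for a in range(3))
            key = (int(levels[p]), length)
            counts[key] = counts.get(key, 0) + 1
    return counts


def brute_glszm(levels: np.ndarray, mask: np.ndarray) -> dict:
    """Zone counts via BFS flood fill over 26-connected equal levels."""
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    counts: dict[tuple[int, int], float] = {}
    for p in zip(*np.nonzero(mask)):
        if visited[p]:
            continue
        level = levels[p]
        size = 0
        queue = deque([p])
        visited[p] = True
        while queue:
            cur = queue.popleft()
            size += 1
            for off in _neighbors26():
                q = tuple(cur[a] + off[a] for a in range(3))
                if (
                    _in(shape, q)
                    and mask[q]
                    and not visited[q]
                    and levels[q] == level
                ):
                    visited[q] = True
                    queue.append(q)
        key = (int(level), size)
        counts[key] = counts.get(key, 0) + 1
    return counts


def brute_gldm(
    levels: np.ndarray, mask: np.ndarray, alpha: float = 0.0, distance: int = 1
) -> dict:
    """Dependence counts: per voxel, the number of in-mask neighbours with
    |level difference| <= alpha; matrix column is the size (count + 1)."""
    shape = levels.shape
    counts: dict[tuple[int, int], float] = {}
    for p in zip(*np.nonzero(mask)):
        dep = 0
        for off in _neighbors26(distance):
            q = tuple(p[a] + off[a] for a in range(3))
            if _in(shape, q) and mask[q] and abs(int(levels[q]) - int(levels[p])) <= alpha:
                dep += 1
        key = (int(levels[p]), dep + 1)
        counts[key] = counts.get(key, 0) + 1
    return counts


def random_roi(rng: np.random.Generator, max_side: int = 4, n_levels: int = 3):
    """Random small discretisable ROI: integer HU values such that the
    fixed-bin discretisation yields levels 1..<=n_levels."""
    shape = tuple(rng.integers(1, max_side + 1, size=3))
    values = rng.integers(0, n_levels, size=shape).astype(float) * 25.0
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask.flat[rng.integers(mask.size)] = True
    return values, mask
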