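"""Grey-level texture matrices: GLCM, GLRLM, GLSZM, GLDM.

Direction convention: the 13 unique 3D offsets of the 26-neighbourhood
modulo inversion, at Chebyshev distance 1 (scaled by the configured
neighbour distance).  GLCM counts are aggregated over all directions and
symmetrised (M + M^T); GLRLM counts are computed per direction and summed;
GLSZM zones use 26-connectivity; GLDM dependence is the number of
neighbours whose level differs by at most alpha.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.ndimage import label

from phantomrad.radiomics.discretise import DiscretisedROI

#: Unique 3D direction offsets (26-neighbourhood modulo inversion).
OFFSETS_13 = tuple(
    off
    for off in itertools.product((1, 0, -1), repeat=3)
    if off > (0, 0, 0)
)
assert len(OFFSETS_13) == 13


def _shift_slices(shape, offset):
    """Slices (center, neighbour) pairing voxel x with x + offset."""
    center, neigh = [], []
    for n, o in zip(shape, offset):
        center.append(slice(max(0, -o), n - max(0, o)))
        neigh.append(slice(max(0, o), n - max(0, -o)))
    return tuple(center), tuple(neigh)


def glcm_matrix(disc: DiscretisedROI, distance: int = 1) -> np.ndarray:
    """Symmetrised co-occurrence counts aggregated over the 13 directions.

    Both voxels of a pair must lie in the mask.  The returned matrix is
    raw counts; feature computation normalises it to sum 1.
    """
    ng = disc.n_levels
    counts = np.zeros((ng, ng), dtype=np.float64)
    lv = disc.levels
    mk = disc.mask
    for off in OFFSETS_13:
        off_d = tuple(o * distance for o in off)
        ctr, ngh = _shift_slices(lv.shape, off_d)
        a = lv[ctr]
        b = lv[ngh]
        valid = mk[ctr] & mk[ngh]
        if not valid.any():
            continue
        flat = (a[valid] - 1) * ng + (b[valid] - 1)
        counts += np.bincount(flat, minlength=ng * ng).reshape(ng, ng)
    return counts + counts.T


def glrlm_matrix(disc: DiscretisedROI) -> np.ndarray:
    """Run-length counts P(level, run length) summed over 13 directions.

    A run is a maximal set of collinear, equal-level, in-mask voxels.
    """
    ng = disc.n_levels
    max_run = max(disc.levels.shape)
    counts = np.zeros((ng, max_run), dtype=np.float64)
    for off in OFFSETS_13:
        structure = np.zeros((3, 3, 3), dtype=bool)
        structure[1, 1, 1] = True
        structure[1 + off[0], 1 + off[1], 1 + off[2]] = True
        structure[1 - off[0], 1 - off[1], 1 - off[2]] = True
        for g in range(1, ng + 1):
            binary = (disc.levels == g) & disc.mask
            if not binary.any():
                continue
            labels, n_runs = label(binary, structure=structure)
            if n_runs == 0:
                continue
            lengths = np.bincount(labels.ravel())[1:]
            counts[g - 1] += np.bincount(lengths, minlength=max_run + 1)[1:]
    # trim trailing all-zero run-length columns
    last = np.nonzero(counts.sum(axis=0))[0]
    width = int(last.max()) + 1 if last.size else 1
    return counts[:, :width]


def glszm_matrix(disc: DiscretisedROI) -> np.ndarray:
    """Size-zone counts P(level, zone size); zones are 26-connected
    components of equal level within the mask."""
    ng = disc.n_levels
    structure = np.ones((3, 3, 3), dtype=bool)
    zone_counts: dict[tuple[int, int], int] = {}
    max_size = 1
    for g in range(1, ng + 1):
        binary = (disc.levels == g) & disc.mask
        if not binary.any():
            continue
        labels, n_zones = label(binary, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        for s in sizes:
            zone_counts[(g, int(s))] = zone_counts.get((g, int(s)), 0) + 1
            max_size = max(max_size, int(s))
    counts = np.zeros((ng, max_size), dtype=np.float64)
    for (g, s), c in zone_counts.items():
        counts[g - 1, s - 1] = c
    return counts


def gldm_matrix(
    disc: DiscretisedROI, alpha: float = 0.0, distance: int = 1
) -> np.ndarray:
    """Dependence counts P(level, dependence size).

    The dependence size of a voxel is 1 (itself) plus the number of
    in-mask neighbours in the 26-neighbourhood whose level differs by at
    most ``alpha``; columns index sizes 1..max.
    """
    lv = disc.levels
    mk = disc.mask
    dep = np.zeros(lv.shape, dtype=np.int64)
    for off in OFFSETS_13:
        for sign in (1, -1):
            off_d = tuple(sign * o * distance for o in off)
            ctr, ngh = _shift_slices(lv.shape, off_d)
            ok = mk[ctr] & mk[ngh] & (np.abs(lv[ctr] - lv[ngh]) <= alpha)
            dep[ctr][ok] += 1
    ng = disc.n_levels
    sizes = dep[mk] + 1
    levels = lv[mk]
    max_size = int(sizes.max())
    counts = np.zeros((ng, max_size), dtype=np.float64)
    flat = (levels - 1) * max_size + (sizes - 1)
    counts += np.bincount(flat, minlength=ng * max_size).reshape(ng, max_size)
    return counts
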