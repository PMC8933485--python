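"""Fixed-bin-width grey-level discretisation of an ROI."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretisedROI:
    """Integer grey levels (1..n_levels) on the ROI's bounding box.

    ``levels`` is 0 outside the mask; the mask encodes which voxels belong
    to the region, so neighbours outside the ROI are simply absent from
    texture-matrix counts.
    """

    levels: np.ndarray  # int array, 0 outside mask
    mask: np.ndarray  # bool, same shape
    n_levels: int
    bin_width: float

    def __post_init__(self) -> None:
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels and mask shapes differ")
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValueError("empty ROI")
        if inside.min() != 1 or inside.max() != self.n_levels:
            raise ValueError("levels must span 1..n_levels inside the mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _bounding_box(mask: np.ndarray) -> tuple[slice, ...]:
    idx = np.nonzero(mask)
    return tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)


def discretise(
    values: np.ndarray, mask: np.ndarray, bin_width: float = 25.0
) -> DiscretisedROI:
    """Assign level ``floor((x - min_ROI) / bin_width) + 1`` to every masked
    voxel: a new bin for every intensity interval of the bin width starting
    at the lowest occurring intensity."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    values = np.asarray(values, dtype=np.float64)
    if values.shape != mask.shape:
        raise ValueError("values and mask shapes differ")

    box = _bounding_box(mask)
    vals = values[box]
    msk = mask[box]
    lo = vals[msk].min()
    levels = np.zeros(vals.shape, dtype=np.int64)
    levels[msk] = np.floor((vals[msk] - lo) / bin_width).astype(np.int64) + 1
    return DiscretisedROI(
        levels=levels,
        mask=msk,
        n_levels=int(levels[msk].max()),
        bin_width=float(bin_width),
    )
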