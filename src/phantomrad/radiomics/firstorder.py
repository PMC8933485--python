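"""First-order (intensity histogram) features."""

from __future__ import annotations

import numpy as np

from phantomrad.radiomics.discretise import discretise

_EPS = np.spacing(1.0)


def first_order_features(
    values: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    bin_width: float = 25.0,
    voxel_array_shift: float = 0.0,
) -> dict[str, float]:
    """The 18 default first-order statistics of the masked voxels.

    Entropy and uniformity are computed on the fixed-bin-width discretised
    histogram; the voxel array shift (default 0) enters only energy and
    RMS.
    """
    mask = np.asarray(mask).astype(bool)
    x = np.asarray(values, dtype=np.float64)[mask]
    if x.size == 0:
        raise ValueError("empty ROI mask")
    n = x.size
    c = voxel_array_shift
    voxel_volume = float(np.prod(spacing))

    disc = discretise(values, mask, bin_width)
    p = np.bincount(disc.levels[disc.mask])[1:] / n

    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    if m2 > 0:
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2
    else:  # constant ROI: moments degenerate, return 0 by convention
        skewness = 0.0
        kurtosis = 0.0

    energy = float(((x + c) ** 2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": float(-np.sum(p * np.log2(p + _EPS))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(((x + c) ** 2).mean())),
        "Skewness": skewness,
        "Kurtosis": kurtosis,
        "Variance": m2,
        "Uniformity": float(np.sum(p**2)),
    }
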