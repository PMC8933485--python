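"""Texture features computed from grey-level matrices.

All formulas follow the standard IBSI-aligned definitions.  Matrices are
normalised to probabilities here; features whose formulas divide by zero
on degenerate (single-level) ROIs return 0 by convention, with a logged
warning at the extraction level.
"""

from __future__ import annotations

import numpy as np

_EPS = np.spacing(1.0)


def _marginal_grids(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ni, nj = P.shape
    return (
        np.arange(1, ni + 1, dtype=np.float64)[:, None],
        np.arange(1, nj + 1, dtype=np.float64)[None, :],
    )


# ----------------------------------------------------------------------
# GLCM


def glcm_features(counts: np.ndarray) -> dict[str, float]:
    """The 22 co-occurrence features from a symmetrised count matrix."""
    ng = counts.shape[0]
    total = counts.sum()
    if total == 0:
        # single-voxel ROI: no valid pairs at all
        p = np.zeros_like(counts)
    else:
        p = counts / total
    i, j = _marginal_grids(p)
    px = p.sum(axis=1)  # == py by symmetry
    lv = np.arange(1, ng + 1, dtype=np.float64)
    mu = float((px * lv).sum())
    sigma2 = float((px * (lv - mu) ** 2).sum())
    sigma = np.sqrt(sigma2)

    # diagonal / cross-diagonal marginals
    ks = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(ks.size)
    kd = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(kd.size)
    sums = (i + j).astype(int)
    diffs = np.abs(i - j).astype(int)
    np.add.at(p_sum, (sums - 2).ravel(), p.ravel())
    np.add.at(p_diff, diffs.ravel(), p.ravel())

    HX = float(-np.sum(px * np.log2(px + _EPS)))
    HXY = float(-np.sum(p * np.log2(p + _EPS)))
    pxpy = px[:, None] * px[None, :]
    HXY1 = float(-np.sum(p * np.log2(pxpy + _EPS)))
    HXY2 = float(-np.sum(pxpy * np.log2(pxpy + _EPS)))

    autocorr = float(np.sum(p * i * j))
    diff_avg = float(np.sum(p_diff * kd))

    if sigma > 0:
        correlation = (autocorr - mu * mu) / (sigma * sigma)
    else:
        correlation = 0.0
    denom_imc = HX  # max(HX, HY), with HX == HY for a symmetric matrix
    imc1 = (HXY - HXY1) / denom_imc if denom_imc > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY)))))

    off_diag = diffs != 0
    inverse_variance = float(
        np.sum(p[off_diag] / (i - j)[off_diag].astype(np.float64) ** 2)
    )

    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": float(np.sum(p * (i + j - 2 * mu) ** 4)),
        "ClusterShade": float(np.sum(p * (i + j - 2 * mu) ** 3)),
        "ClusterTendency": float(np.sum(p * (i + j - 2 * mu) ** 2)),
        "Contrast": float(np.sum(p * (i - j) ** 2)),
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(p_diff * np.log2(p_diff + _EPS))),
        "DifferenceVariance": float(np.sum(p_diff * (kd - diff_avg) ** 2)),
        "Id": float(np.sum(p / (1.0 + np.abs(i - j)))),
        "Idm": float(np.sum(p / (1.0 + (i - j) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((i - j) / ng) ** 2))),
        "Idn": float(np.sum(p / (1.0 + np.abs(i - j) / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inverse_variance,
        "JointAverage": mu,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": HXY,
        "MaximumProbability": float(p.max()) if p.size else 0.0,
        "SumEntropy": float(-np.sum(p_sum * np.log2(p_sum + _EPS))),
        "SumSquares": float(np.sum(p * (i - mu) ** 2)),
    }


# ----------------------------------------------------------------------
# run-length / size-zone shared machinery


def _rl_style_features(P: np.ndarray) -> dict[str, float]:
    """Shared emphasis/nonuniformity/variance terms for matrices indexed
    (grey level, size-like quantity)."""
    Nz = P.sum()
    if Nz == 0:
        raise ValueError("empty texture matrix")
    p = P / Nz
    i, s = _marginal_grids(P)
    pg = p.sum(axis=1)  # grey-level marginal
    ps = p.sum(axis=0)  # size marginal
    lv = np.arange(1, P.shape[0] + 1, dtype=np.float64)
    sz = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    mu_g = float((pg * lv).sum())
    mu_s = float((ps * sz).sum())
    return {
        "Nz": float(Nz),
        "small": float(np.sum(p / s**2)),
        "large": float(np.sum(p * s**2)),
        "low": float(np.sum(p / i**2)),
        "high": float(np.sum(p * i**2)),
        "small_low": float(np.sum(p / (i**2 * s**2))),
        "small_high": float(np.sum(p * i**2 / s**2)),
        "large_low": float(np.sum(p * s**2 / i**2)),
        "large_high": float(np.sum(p * i**2 * s**2)),
        "gln": float(np.sum((P.sum(axis=1)) ** 2) / Nz),
        "glnn": float(np.sum(pg**2)),
        "sn": float(np.sum((P.sum(axis=0)) ** 2) / Nz),
        "snn": float(np.sum(ps**2)),
        "gl_var": float(np.sum(pg * (lv - mu_g) ** 2)),
        "size_var": float(np.sum(ps * (sz - mu_s) ** 2)),
        "entropy": float(-np.sum(p * np.log2(p + _EPS))),
    }


def glrlm_features(
    P: np.ndarray, n_voxels: int, n_directions: int = 13
) -> dict[str, float]:
    """The 16 run-length features; run percentage uses the total voxel
    count times the number of directions as the maximum run count."""
    t = _rl_style_features(P)
    return {
        "GrayLevelNonUniformity": t["gln"],
        "GrayLevelNonUniformityNormalized": t["glnn"],
        "GrayLevelVariance": t["gl_var"],
        "HighGrayLevelRunEmphasis": t["high"],
        "LongRunEmphasis": t["large"],
        "LongRunHighGrayLevelEmphasis": t["large_high"],
        "LongRunLowGrayLevelEmphasis": t["large_low"],
        "LowGrayLevelRunEmphasis": t["low"],
        "RunEntropy": t["entropy"],
        "RunLengthNonUniformity": t["sn"],
        "RunLengthNonUniformityNormalized": t["snn"],
        "RunPercentage": t["Nz"] / (n_voxels * n_directions),
        "RunVariance": t["size_var"],
        "ShortRunEmphasis": t["small"],
        "ShortRunHighGrayLevelEmphasis": t["small_high"],
        "ShortRunLowGrayLevelEmphasis": t["small_low"],
    }


def glszm_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 size-zone features."""
    t = _rl_style_features(P)
    return {
        "GrayLevelNonUniformity": t["gln"],
        "GrayLevelNonUniformityNormalized": t["glnn"],
        "GrayLevelVariance": t["gl_var"],
        "HighGrayLevelZoneEmphasis": t["high"],
        "LargeAreaEmphasis": t["large"],
        "LargeAreaHighGrayLevelEmphasis": t["large_high"],
        "LargeAreaLowGrayLevelEmphasis": t["large_low"],
        "LowGrayLevelZoneEmphasis": t["low"],
        "SizeZoneNonUniformity": t["sn"],
        "SizeZoneNonUniformityNormalized": t["snn"],
        "SmallAreaEmphasis": t["small"],
        "SmallAreaHighGrayLevelEmphasis": t["small_high"],
        "SmallAreaLowGrayLevelEmphasis": t["small_low"],
        "ZoneEntropy": t["entropy"],
        "ZonePercentage": t["Nz"] / n_voxels,
        "ZoneVariance": t["size_var"],
    }


def gldm_features(P: np.ndarray) -> dict[str, float]:
    """The 14 dependence features; columns index dependence sizes 1..max."""
    t = _rl_style_features(P)
    return {
        "DependenceEntropy": t["entropy"],
        "DependenceNonUniformity": t["sn"],
        "DependenceNonUniformityNormalized": t["snn"],
        "DependenceVariance": t["size_var"],
        "GrayLevelNonUniformity": t["gln"],
        "GrayLevelVariance": t["gl_var"],
        "HighGrayLevelEmphasis": t["high"],
        "LargeDependenceEmphasis": t["large"],
        "LargeDependenceHighGrayLevelEmphasis": t["large_high"],
        "LargeDependenceLowGrayLevelEmphasis": t["large_low"],
        "LowGrayLevelEmphasis": t["low"],
        "SmallDependenceEmphasis": t["small"],
        "SmallDependenceHighGrayLevelEmphasis": t["small_high"],
        "SmallDependenceLowGrayLevelEmphasis": t["small_low"],
    }
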