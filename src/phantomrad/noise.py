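"""Poisson sinogram noise and noise-level calibration.

The noise level A is the inverse of the background photon intensity I0.
Each detector pixel of a noiseless sinogram I_image is replaced by

    k ~ Poisson(I0 * exp(-I_image)),     I_final = -log(k / I0),

with zero counts clamped to one photon before the log (standard low-dose
practice; the limit A -> 0 recovers I_image exactly).  Calibration fits
the approximately linear relation between the reconstructed image-domain
variance sigma^2 and A, and inverts it to find the A matching a target
variance (e.g. one measured from repeated real acquisitions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from phantomrad.phantom import ROIMask, VoxelVolume
from phantomrad.projection import Sinogram


@dataclass
class NoiseModel:
    """Poisson noise level A = 1/I0; A = 0 means noiseless passthrough."""

    A: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError(f"noise level A must be >= 0, got {self.A}")

    @property
    def I0(self) -> float:
        if self.A == 0:
            return np.inf
        return 1.0 / self.A


def add_poisson_noise(sinogram: Sinogram, model: NoiseModel) -> Sinogram:
    """Sample per-pixel Poisson counts and return the log-normalized
    noisy sinogram.  Deterministic given ``model.seed``; draws are taken
    from one generator in row-major pixel order."""
    if sinogram.noisy:
        raise ValueError("sinogram is already noisy")
    if np.any(sinogram.data < 0):
        raise ValueError("noiseless sinogram must be nonnegative (I_image >= 0)")
    if model.A == 0:
        return Sinogram(sinogram.data.copy(), sinogram.geometry, noisy=False)

    rng = np.random.default_rng(model.seed)
    I0 = model.I0
    lam = I0 * np.exp(-sinogram.data)
    k = rng.poisson(lam).astype(np.float64)
    np.maximum(k, 1.0, out=k)  # zero-count clamp: -log(0) undefined
    final = -np.log(k / I0)
    return Sinogram(final, sinogram.geometry, noisy=True)


def pixelwise_variance(
    volumes: list[VoxelVolume],
    support: ROIMask | np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Unbiased per-voxel variance across repeated reconstructions and its
    mean over the support voxels (whole grid if no support is given)."""
    if len(volumes) < 2:
        raise ValueError("at least two repeated volumes are required")
    shape = volumes[0].shape
    for v in volumes[1:]:
        if v.shape != shape:
            raise ValueError("repeated volumes must share one grid")
    stack = np.stack([v.values for v in volumes])
    var_map = stack.var(axis=0, ddof=1)
    if support is None:
        mean_sigma2 = float(var_map.mean())
    else:
        mask = support.mask if isinstance(support, ROIMask) else np.asarray(support)
        mask = mask.astype(bool)
        if mask.shape != shape:
            raise ValueError("support mask not congruent with volumes")
        if not mask.any():
            raise ValueError("empty support mask")
        mean_sigma2 = float(var_map[mask].mean())
    return mean_sigma2, var_map


@dataclass
class CalibrationPoint:
    """One (noise level, reconstructed variance) measurement."""

    A: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")


@dataclass
class CalibrationFit:
    """Ordinary least squares line sigma^2 = slope * A + intercept."""

    slope: float
    intercept: float
    residual: float
    points: list[CalibrationPoint] = field(default_factory=list)

    def predict(self, A: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(A) + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "residual": self.residual,
            "points": [{"A": p.A, "sigma2": p.sigma2} for p in self.points],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CalibrationFit":
        return cls(
            slope=payload["slope"],
            intercept=payload["intercept"],
            residual=payload["residual"],
            points=[CalibrationPoint(p["A"], p["sigma2"]) for p in payload["points"]],
        )


def fit_variance_vs_A(points: list[CalibrationPoint]) -> CalibrationFit:
    """OLS fit of sigma^2 against A over the calibration points."""
    if len(points) < 2:
        raise ValueError("at least two calibration points are required")
    A = np.array([p.A for p in points], dtype=float)
    s2 = np.array([p.sigma2 for p in points], dtype=float)
    if np.allclose(A, A[0]):
        raise ValueError("degenerate fit: all calibration points share one A")
    slope, intercept = np.polyfit(A, s2, deg=1)
    residual = float(np.sum((slope * A + intercept - s2) ** 2))
    return CalibrationFit(float(slope), float(intercept), residual, list(points))


def solve_A_for_variance(fit: CalibrationFit, target_sigma2: float) -> float:
    """Crossing point of the fitted line with a horizontal variance target."""
    if fit.slope == 0:
        raise ValueError("zero slope: the fitted line never crosses the target")
    A = (target_sigma2 - fit.intercept) / fit.slope
    if A < 0:
        raise ValueError(
            f"target variance {target_sigma2} is below the achievable range "
            f"(implied A = {A:.3g} < 0)"
        )
    return float(A)
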