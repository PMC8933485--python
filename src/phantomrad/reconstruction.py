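"""Filtered back-projection (FDK-style) and SIRT reconstruction.

Both algorithms reconstruct the attenuation volume from a (possibly noisy)
sinogram and convert it back to HU.  FBP cosine-weights the projections,
ramp-filters detector rows in the frequency domain, and performs a
distance-weighted voxel-driven backprojection; for helical data at pitch 1
the FDK short-object approximation is accepted (contributions are averaged
over rotations).  SIRT iterates

    x_{k+1} = x_k + C P^T R (b - P x_k)

with R and C the inverse row/column sums of the system matrix, starting
from zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from phantomrad.geometry import ProjectionGeometry
from phantomrad.phantom import VoxelVolume
from phantomrad.projection import (
    AttenuationModel,
    Grid,
    Sinogram,
    get_projector,
    mu_to_hu,
)


@dataclass
class ReconSpec:
    """Reconstruction algorithm selection and parameters."""

    algorithm: str = "fbp"  # "fbp" | "sirt"
    n_iterations: int = 500  # SIRT only
    filter: str = "ramp"  # FBP only (Ram-Lak, no apodization)
    nonnegative: bool = False  # optional SIRT constraint

    def __post_init__(self) -> None:
        self.algorithm = self.algorithm.lower()
        if self.algorithm not in ("fbp", "sirt"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "sirt" and self.n_iterations < 1:
            raise ValueError("SIRT requires n_iterations >= 1")
        if self.filter != "ramp":
            raise ValueError("only the ramp (Ram-Lak) filter is provided")


def _ramp_kernel(n: int, du: float) -> np.ndarray:
    """Discrete Ram-Lak convolution kernel (Kak & Slaney band-limited
    form) sampled at detector pitch ``du``."""
    idx = np.arange(-n + 1, n)
    h = np.zeros(idx.shape, dtype=np.float64)
    h[idx == 0] = 1.0 / (4.0 * du * du)
    odd = idx % 2 != 0
    h[odd] = -1.0 / (np.pi * idx[odd] * du) ** 2
    return h


def _filter_rows(data: np.ndarray, du: float) -> np.ndarray:
    """Convolve each detector row (last axis) with the ramp kernel."""
    n = data.shape[-1]
    kernel = _ramp_kernel(n, du)
    size = n + kernel.size - 1
    nfft = 1 << int(np.ceil(np.log2(size)))
    K = np.fft.rfft(kernel, nfft)
    D = np.fft.rfft(data, nfft, axis=-1)
    conv = np.fft.irfft(D * K, nfft, axis=-1)
    # 'same' part of the convolution, scaled by the sampling step
    return conv[..., n - 1 : 2 * n - 1] * du


def fbp_reconstruct(
    sinogram: Sinogram,
    geometry: ProjectionGeometry,
    grid: Grid | VoxelVolume,
    spec: ReconSpec | None = None,
    model: AttenuationModel | None = None,
) -> VoxelVolume:
    """FDK-style filtered back-projection onto ``grid``, output in HU."""
    spec = spec or ReconSpec(algorithm="fbp")
    if spec.algorithm != "fbp":
        raise ValueError("spec.algorithm must be 'fbp'")
    if isinstance(grid, VoxelVolume):
        grid = Grid.from_volume(grid)
    if sinogram.geometry.cache_key() != geometry.cache_key():
        raise ValueError("sinogram geometry does not match the supplied geometry")
    n_views = geometry.n_projections
    if n_views < 2:
        warnings.warn("fewer than 2 views: reconstruction is under-determined",
                      stacklevel=2)

    sod = geometry.source_to_isocenter
    sdd = geometry.source_to_detector
    rows_d, cols_d = geometry.det_shape
    pixel = geometry.pixel_pitch
    mag = sdd / sod

    # detector coordinates rescaled to the isocenter plane (virtual
    # detector through the rotation axis)
    u = (np.arange(cols_d) - (cols_d - 1) / 2.0) * pixel / mag
    v = (np.arange(rows_d) - (rows_d - 1) / 2.0) * pixel / mag
    du = pixel / mag
    cosw = sod / np.sqrt(sod**2 + u[None, :] ** 2 + v[:, None] ** 2)

    filtered = _filter_rows(sinogram.data * cosw[None, :, :], du)

    # angular extent: multiple helical rotations re-cover each voxel, so
    # contributions are averaged over rotations (short-object FDK).
    n_rot = max(1, int(round(_total_angle(geometry) / (2.0 * np.pi))))
    dbeta = _total_angle(geometry) / n_views
    scale = dbeta / (2.0 * n_rot)

    cx, cy, cz = grid.voxel_centers()
    X = cx[:, None, None]
    Y = cy[None, :, None]
    Z = cz[None, None, :]
    recon = np.zeros(grid.shape, dtype=np.float64)

    for view in range(n_views):
        s = geometry.src[view]
        dc = geometry.det_center[view]
        u_hat = geometry.det_u[view] / pixel
        v_hat = geometry.det_v[view] / pixel
        c_hat = dc - s
        c_hat = c_hat / np.linalg.norm(c_hat)

        dx, dy, dz = X - s[0], Y - s[1], Z - s[2]
        U = dx * c_hat[0] + dy * c_hat[1] + dz * c_hat[2]  # depth along central ray
        with np.errstate(divide="ignore", invalid="ignore"):
            t = sdd / U
            # intersection with the detector plane, in isocenter units
            uu = (dx * u_hat[0] + dy * u_hat[1] + dz * u_hat[2]) * t / mag
            vv = (dx * v_hat[0] + dy * v_hat[1] + dz * v_hat[2]) * t / mag
        fu = uu / du + (cols_d - 1) / 2.0
        fv = vv / du + (rows_d - 1) / 2.0
        sample = _bilinear(filtered[view], fv, fu)
        w = np.where(U > 0, (sod / np.where(U > 0, U, 1.0)) ** 2, 0.0)
        recon += w * sample

    recon *= scale
    mu = VoxelVolume(recon, grid.spacing, grid.origin)
    return mu_to_hu(mu, model)


def _total_angle(geometry: ProjectionGeometry) -> float:
    """Total angular span implied by uniformly spaced views."""
    a0 = np.arctan2(-geometry.src[0, 1], -geometry.src[0, 0])
    if geometry.n_projections == 1:
        return 2.0 * np.pi
    a1 = np.arctan2(-geometry.src[1, 1], -geometry.src[1, 0])
    step = (a1 - a0) % (2.0 * np.pi)
    if step == 0:
        step = 2.0 * np.pi / geometry.n_projections
    return step * geometry.n_projections


def _bilinear(img: np.ndarray, fr: np.ndarray, fc: np.ndarray) -> np.ndarray:
    """Bilinear sampling of a 2D image at fractional (row, col); zero
    outside."""
    rows, cols = img.shape
    r0 = np.floor(fr).astype(np.int64)
    c0 = np.floor(fc).astype(np.int64)
    wr = fr - r0
    wc = fc - c0
    out = np.zeros(np.broadcast(fr, fc).shape, dtype=np.float64)
    for dr, wgt_r in ((0, 1.0 - wr), (1, wr)):
        rr = r0 + dr
        ok_r = (rr >= 0) & (rr < rows)
        for dcol, wgt_c in ((0, 1.0 - wc), (1, wc)):
            cc = c0 + dcol
            ok = ok_r & (cc >= 0) & (cc < cols)
            if not ok.any():
                continue
            w = wgt_r * wgt_c
            out[ok] += w[ok] * img[rr[ok], cc[ok]]
    return out


def sirt_reconstruct(
    sinogram: Sinogram,
    geometry: ProjectionGeometry,
    grid: Grid | VoxelVolume,
    spec: ReconSpec | None = None,
    model: AttenuationModel | None = None,
) -> VoxelVolume:
    """SIRT with inverse row/column-sum preconditioning, zero init,
    ``spec.n_iterations`` sweeps (default 500); output in HU."""
    spec = spec or ReconSpec(algorithm="sirt")
    if spec.algorithm != "sirt":
        raise ValueError("spec.algorithm must be 'sirt'")
    if isinstance(grid, VoxelVolume):
        grid = Grid.from_volume(grid)
    if sinogram.geometry.cache_key() != geometry.cache_key():
        raise ValueError("sinogram geometry does not match the supplied geometry")

    proj = get_projector(geometry, grid)
    b = sinogram.data.ravel()
    with np.errstate(divide="ignore"):
        R = np.where(proj.row_sums > 0, 1.0 / proj.row_sums, 0.0)
        C = np.where(proj.col_sums > 0, 1.0 / proj.col_sums, 0.0)

    x = np.zeros(int(np.prod(grid.shape)), dtype=np.float64)
    A = proj.matrix
    r0_norm = None
    for it in range(spec.n_iterations):
        r = b - A @ x
        x += C * (A.T @ (R * r))
        if spec.nonnegative:
            np.clip(x, 0.0, None, out=x)
        if it % 25 == 0:
            r_norm = float(np.linalg.norm(r))
            if r0_norm is None:
                r0_norm = r_norm
            elif r0_norm > 0 and r_norm > 10.0 * r0_norm:
                raise RuntimeError(
                    f"SIRT diverged at iteration {it}: residual {r_norm:.3e} "
                    f"> 10 x initial {r0_norm:.3e}"
                )
    mu = VoxelVolume(x.reshape(grid.shape), grid.spacing, grid.origin)
    return mu_to_hu(mu, model)


def reconstruct(
    sinogram: Sinogram,
    geometry: ProjectionGeometry,
    grid: Grid | VoxelVolume,
    spec: ReconSpec,
    model: AttenuationModel | None = None,
) -> VoxelVolume:
    """Dispatch on ``spec.algorithm``."""
    if spec.algorithm == "fbp":
        return fbp_reconstruct(sinogram, geometry, grid, spec, model)
    return sirt_reconstruct(sinogram, geometry, grid, spec, model)
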