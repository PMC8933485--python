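"""Cone-beam forward projection and its exact adjoint.

Rays are traced from the source through every detector pixel with Joseph's
method: one sample per voxel plane along the ray's dominant axis, bilinear
interpolation in the two transverse axes, weights scaled by the oblique
path length.  The per-geometry system matrix is materialised as a sparse
CSR operator, which makes ``apply_adjoint`` the literal matrix transpose
of ``forward_project`` and gives SIRT its row/column sums for free.

Matrices are cached per (geometry, grid) pair; a full 512^2-detector
helical scan on a large grid is memory-hungry, so study-scale runs use
reduced detectors/grids (see the pipeline presets).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from phantomrad.geometry import ProjectionGeometry
from phantomrad.phantom import VoxelVolume


@dataclass
class AttenuationModel:
    """Linear HU -> attenuation conversion; water at 120 kVp by default."""

    mu_water: float = 0.0192  # mm^-1

    def __post_init__(self) -> None:
        if self.mu_water <= 0:
            raise ValueError("mu_water must be positive")


def hu_to_mu(volume: VoxelVolume, model: AttenuationModel | None = None) -> VoxelVolume:
    """mu = mu_water * (1 + HU/1000), clamped at zero."""
    model = model or AttenuationModel()
    mu = model.mu_water * (1.0 + volume.values / 1000.0)
    np.clip(mu, 0.0, None, out=mu)
    return volume.like(mu)


def mu_to_hu(volume: VoxelVolume, model: AttenuationModel | None = None) -> VoxelVolume:
    """Inverse of :func:`hu_to_mu` (no clamping)."""
    model = model or AttenuationModel()
    return volume.like(1000.0 * (volume.values / model.mu_water - 1.0))


@dataclass
class Sinogram:
    """Stack of projection images of line integrals (mu * mm)."""

    data: np.ndarray  # (n_projections, rows, cols)
    geometry: ProjectionGeometry
    noisy: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        rows, cols = self.geometry.det_shape
        expected = (self.geometry.n_projections, rows, cols)
        if self.data.shape != expected:
            raise ValueError(
                f"sinogram shape {self.data.shape} does not match geometry {expected}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram data must be finite")


@dataclass(frozen=True)
class Grid:
    """Reconstruction/projection voxel grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    @classmethod
    def from_volume(cls, volume: VoxelVolume) -> "Grid":
        return cls(volume.shape, volume.spacing, volume.origin)

    def voxel_centers(self) -> tuple[np.ndarray, ...]:
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )

    def cache_key(self) -> tuple:
        return (self.shape, self.spacing, self.origin)


class Projector:
    """Sparse-matrix realization of the cone-beam projection operator."""

    def __init__(self, geometry: ProjectionGeometry, grid: Grid):
        self.geometry = geometry
        self.grid = grid
        self.matrix = self._build()

    # ------------------------------------------------------------------
    def _build(self) -> sp.csr_matrix:
        geom, grid = self.geometry, self.grid
        shape = grid.shape
        spacing = np.asarray(grid.spacing)
        origin = np.asarray(grid.origin)
        rows_d, cols_d = geom.det_shape
        rays_per_view = rows_d * cols_d
        n_vox = int(np.prod(shape))
        strides = np.array(
            [shape[1] * shape[2], shape[2], 1], dtype=np.int64
        )  # C-order flat index

        ent_rows, ent_cols, ent_vals = [], [], []
        for view in range(geom.n_projections):
            s = geom.src[view]
            pix = geom.pixel_positions(view).reshape(-1, 3)
            d = pix - s  # world-space ray directions
            qs = (s - origin) / spacing - 0.5  # index-space source
            dq = d / spacing
            dominant = np.argmax(np.abs(dq), axis=1)

            for a in range(3):
                ray_ids = np.nonzero(dominant == a)[0]
                if ray_ids.size == 0:
                    continue
                b, c = [ax for ax in range(3) if ax != a]
                n_a = shape[a]
                dq_r = dq[ray_ids]
                # one sample per integer voxel plane along the dominant axis
                k = np.arange(n_a, dtype=np.float64)
                t = (k[None, :] - qs[a]) / dq_r[:, a][:, None]  # (nr, n_a)
                qb = qs[b] + t * dq_r[:, b][:, None]
                qc = qs[c] + t * dq_r[:, c][:, None]
                ib0 = np.floor(qb).astype(np.int64)
                ic0 = np.floor(qc).astype(np.int64)
                fb = qb - ib0
                fc = qc - ic0
                seg = spacing[a] * np.linalg.norm(d[ray_ids], axis=1) / np.abs(
                    d[ray_ids, a]
                )  # oblique path length per plane, mm
                ahead = t > 0.0  # only integrate in front of the source

                base_row = view * rays_per_view + ray_ids
                row_grid = np.broadcast_to(base_row[:, None], t.shape)
                k_grid = np.broadcast_to(
                    np.arange(n_a, dtype=np.int64)[None, :], t.shape
                )
                seg_grid = np.broadcast_to(seg[:, None], t.shape)

                for db, wc_b in ((0, 1.0 - fb), (1, fb)):
                    ib = ib0 + db
                    ok_b = (ib >= 0) & (ib < shape[b])
                    for dc, wc_c in ((0, 1.0 - fc), (1, fc)):
                        ic = ic0 + dc
                        ok = ahead & ok_b & (ic >= 0) & (ic < shape[c])
                        if not ok.any():
                            continue
                        w = (wc_b * wc_c * seg_grid)[ok]
                        nz = w > 0
                        if not nz.any():
                            continue
                        flat = (
                            k_grid[ok] * strides[a]
                            + ib[ok] * strides[b]
                            + ic[ok] * strides[c]
                        )
                        ent_rows.append(row_grid[ok][nz].astype(np.int64))
                        ent_cols.append(flat[nz])
                        ent_vals.append(w[nz])

        n_rays = geom.n_projections * rays_per_view
        if ent_rows:
            rows = np.concatenate(ent_rows)
            cols = np.concatenate(ent_cols)
            vals = np.concatenate(ent_vals)
        else:  # volume entirely outside every ray
            rows = np.empty(0, dtype=np.int64)
            cols = np.empty(0, dtype=np.int64)
            vals = np.empty(0)
        mat = sp.coo_matrix((vals, (rows, cols)), shape=(n_rays, n_vox))
        return mat.tocsr()

    # ------------------------------------------------------------------
    def forward(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=np.float64)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"volume shape {values.shape} does not match grid {self.grid.shape}"
            )
        rows_d, cols_d = self.geometry.det_shape
        out = self.matrix @ values.ravel()
        return out.reshape(self.geometry.n_projections, rows_d, cols_d)

    def adjoint(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=np.float64)
        rows_d, cols_d = self.geometry.det_shape
        expected = (self.geometry.n_projections, rows_d, cols_d)
        if data.shape != expected:
            raise ValueError(f"sinogram shape {data.shape} does not match {expected}")
        out = self.matrix.T @ data.ravel()
        return out.reshape(self.grid.shape)

    @property
    def row_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    @property
    def col_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()


# ----------------------------------------------------------------------
# cached access

_PROJECTOR_CACHE: OrderedDict[tuple, Projector] = OrderedDict()
_CACHE_SIZE = 6


def get_projector(geometry: ProjectionGeometry, grid: Grid) -> Projector:
    key = (geometry.cache_key(), grid.cache_key())
    if key in _PROJECTOR_CACHE:
        _PROJECTOR_CACHE.move_to_end(key)
        return _PROJECTOR_CACHE[key]
    proj = Projector(geometry, grid)
    _PROJECTOR_CACHE[key] = proj
    while len(_PROJECTOR_CACHE) > _CACHE_SIZE:
        _PROJECTOR_CACHE.popitem(last=False)
    return proj


def forward_project(mu_volume: VoxelVolume, geometry: ProjectionGeometry) -> Sinogram:
    """Line integrals of the attenuation volume along every source-pixel ray."""
    proj = get_projector(geometry, Grid.from_volume(mu_volume))
    return Sinogram(proj.forward(mu_volume.values), geometry, noisy=False)


def apply_adjoint(
    sinogram: Sinogram, geometry: ProjectionGeometry, grid: Grid | VoxelVolume
) -> VoxelVolume:
    """True adjoint of :func:`forward_project` on the given grid."""
    if isinstance(grid, VoxelVolume):
        grid = Grid.from_volume(grid)
    if sinogram.geometry.cache_key() != geometry.cache_key():
        raise ValueError("sinogram geometry does not match the supplied geometry")
    proj = get_projector(geometry, grid)
    values = proj.adjoint(sinogram.data)
    return VoxelVolume(values, grid.spacing, grid.origin)
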