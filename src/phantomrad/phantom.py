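"""Digital abdominal phantom generation and NIfTI I/O.

The synthetic phantom emulates a printed anthropomorphic abdominal section:
an elliptical body of soft tissue containing six annotated regions of
interest in four tissue classes (two normal liver regions, two cysts, one
hemangioma, one metastasis).  All voxel values are confined to the printable
range of -100..1000 HU.  Tissue texture is realised as seeded, spatially
correlated Gaussian random fields added to each region's mean HU.

Coordinate convention (used package-wide): voxel indices are 0-based and
``world = origin + (index + 0.5) * spacing`` (voxel-center convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

#: Printable HU range of the phantom material.
HU_MIN = -100.0
HU_MAX = 1000.0

TISSUE_CLASSES = ("normal_liver", "cyst", "hemangioma", "metastasis")


@dataclass
class VoxelVolume:
    """A 3D scalar grid with spacing/origin metadata.

    Values are in HU for phantoms and reconstructions, or in mm^-1 for
    attenuation volumes derived from them.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.values.ndim}D")
        if min(self.values.shape) < 1:
            raise ValueError("all volume dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )

    def like(self, values: np.ndarray) -> "VoxelVolume":
        """New volume with the same grid metadata."""
        return VoxelVolume(values, self.spacing, self.origin)


@dataclass
class ROIMask:
    """Binary region-of-interest mask congruent with a :class:`VoxelVolume`."""

    mask: np.ndarray
    name: str
    tissue_class: str

    #: Minimum voxel count: a 3x3x3 neighbourhood is the smallest region on
    #: which all 13 3D texture directions are defined.
    MIN_VOXELS = 27

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(
                f"unknown tissue class {self.tissue_class!r}; "
                f"expected one of {TISSUE_CLASSES}"
            )
        n = int(self.mask.sum())
        if n == 0:
            raise ValueError(f"empty ROI {self.name!r}")
        if n < self.MIN_VOXELS:
            raise ValueError(
                f"ROI {self.name!r} has {n} voxels; at least "
                f"{self.MIN_VOXELS} are required for 3D texture analysis"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ROISpec:
    """Placement and texture of one ellipsoidal region."""

    name: str
    tissue_class: str
    center: tuple[float, float, float]  # mm, world coordinates
    radii: tuple[float, float, float]  # mm
    mean_hu: float
    texture_amplitude: float  # HU (std of the correlated field)
    correlation_length: float = 3.0  # mm

    def validate(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"ROI {self.name!r}: radii must be positive")
        lo = self.mean_hu - self.texture_amplitude
        hi = self.mean_hu + self.texture_amplitude
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(
                f"ROI {self.name!r}: mean {self.mean_hu} +/- amplitude "
                f"{self.texture_amplitude} HU exceeds the printable range "
                f"[{HU_MIN:g}, {HU_MAX:g}] HU"
            )


@dataclass
class PhantomSpec:
    """Full description of a synthetic phantom."""

    shape: tuple[int, int, int] = (128, 128, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    body_radii_fraction: tuple[float, float, float] = (0.45, 0.45, 0.49)
    body_mean_hu: float = 40.0
    body_texture_amplitude: float = 10.0
    body_correlation_length: float = 3.0
    background_hu: float = HU_MIN
    rois: list[ROISpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (HU_MIN <= self.background_hu <= HU_MAX):
            raise ValueError("background HU outside the printable range")
        lo = self.body_mean_hu - self.body_texture_amplitude
        hi = self.body_mean_hu + self.body_texture_amplitude
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError("body HU outside the printable range")
        for roi in self.rois:
            roi.validate()

    # ------------------------------------------------------------------
    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def origin(self) -> tuple[float, float, float]:
        # grid centered on the rotation axis (world origin)
        return tuple(-e / 2.0 for e in self.extent)

    @classmethod
    def default(
        cls,
        shape: tuple[int, int, int] = (128, 128, 64),
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
        seed: int = 0,
    ) -> "PhantomSpec":
        """Six-ROI abdominal layout: 2 normal liver, 2 cysts, 1 hemangioma,
        1 metastasis, with class-distinct mean HU and texture."""
        ex, ey, ez = (n * s for n, s in zip(shape, spacing))
        r_xy = 0.10 * min(ex, ey)
        # For single-slice (2D fast mode) grids the z radius must still
        # cover the one voxel plane.
        r_z = max(0.25 * ez, 1.01 * spacing[2]) if shape[2] > 1 else 1.01 * spacing[2]

        def roi(name, cls_, fx, fy, mean, amp):
            return ROISpec(
                name=name,
                tissue_class=cls_,
                center=(fx * ex, fy * ey, 0.0),
                radii=(r_xy, r_xy, r_z),
                mean_hu=mean,
                texture_amplitude=amp,
            )

        rois = [
            roi("liver_1", "normal_liver", -0.22, -0.17, 60.0, 14.0),
            roi("liver_2", "normal_liver", 0.22, -0.17, 60.0, 14.0),
            roi("cyst_1", "cyst", -0.24, 0.16, 10.0, 8.0),
            roi("cyst_2", "cyst", 0.24, 0.16, 10.0, 8.0),
            roi("hemangioma", "hemangioma", 0.0, 0.27, 130.0, 20.0),
            roi("metastasis", "metastasis", 0.0, -0.28, 90.0, 26.0),
        ]
        return cls(shape=tuple(shape), spacing=tuple(spacing), rois=rois, seed=seed)

    # ------------------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "body_radii_fraction": list(self.body_radii_fraction),
            "body_mean_hu": self.body_mean_hu,
            "body_texture_amplitude": self.body_texture_amplitude,
            "body_correlation_length": self.body_correlation_length,
            "background_hu": self.background_hu,
            "seed": self.seed,
            "rois": [
                {
                    "name": r.name,
                    "tissue_class": r.tissue_class,
                    "center": list(r.center),
                    "radii": list(r.radii),
                    "mean_hu": r.mean_hu,
                    "texture_amplitude": r.texture_amplitude,
                    "correlation_length": r.correlation_length,
                }
                for r in self.rois
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        payload = json.loads(Path(path).read_text())
        rois = [
            ROISpec(
                name=r["name"],
                tissue_class=r["tissue_class"],
                center=tuple(r["center"]),
                radii=tuple(r["radii"]),
                mean_hu=r["mean_hu"],
                texture_amplitude=r["texture_amplitude"],
                correlation_length=r.get("correlation_length", 3.0),
            )
            for r in payload["rois"]
        ]
        return cls(
            shape=tuple(payload["shape"]),
            spacing=tuple(payload["spacing"]),
            body_radii_fraction=tuple(payload["body_radii_fraction"]),
            body_mean_hu=payload["body_mean_hu"],
            body_texture_amplitude=payload["body_texture_amplitude"],
            body_correlation_length=payload["body_correlation_length"],
            background_hu=payload["background_hu"],
            rois=rois,
            seed=payload["seed"],
        )


# ----------------------------------------------------------------------
# generation


def _correlated_field(
    rng: np.random.Generator,
    shape: Sequence[int],
    spacing: Sequence[float],
    correlation_length: float,
    amplitude: float,
) -> np.ndarray:
    """Seeded Gaussian random field smoothed to the given correlation
    length (mm) and rescaled to the requested standard deviation (HU)."""
    white = rng.standard_normal(shape)
    if amplitude == 0:
        return np.zeros(shape)
    sigma_vox = [correlation_length / s for s in spacing]
    # single-voxel axes cannot carry correlation structure
    sigma_vox = [sv if n > 1 else 0.0 for sv, n in zip(sigma_vox, shape)]
    smooth = gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    std = smooth.std()
    if std == 0:
        return np.zeros(shape)
    return smooth * (amplitude / std)


def _ellipsoid_mask(
    volume_shape: Sequence[int],
    spacing: Sequence[float],
    origin: Sequence[float],
    center: Sequence[float],
    radii: Sequence[float],
) -> np.ndarray:
    coords = [
        origin[a] + (np.arange(volume_shape[a]) + 0.5) * spacing[a] for a in range(3)
    ]
    dist2 = sum(
        ((coords[a].reshape([-1 if i == a else 1 for i in range(3)]) - center[a])
         / radii[a]) ** 2
        for a in range(3)
    )
    return dist2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, list[ROIMask]]:
    """Generate the phantom volume and its ROI masks.

    Deterministic given ``spec.seed``.  Raises if any two ROIs overlap,
    if an ROI leaves the body support, or if HU parameters violate the
    printable range (checked by :class:`PhantomSpec` on construction).
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing, origin = spec.shape, spec.spacing, spec.origin

    # semi-axes as fractions of the full grid extent
    body_radii = tuple(
        f * e for f, e in zip(spec.body_radii_fraction, spec.extent)
    )
    body = _ellipsoid_mask(shape, spacing, origin, (0.0, 0.0, 0.0), body_radii)

    values = np.full(shape, spec.background_hu, dtype=np.float64)
    body_field = _correlated_field(
        rng, shape, spacing, spec.body_correlation_length, spec.body_texture_amplitude
    )
    values[body] = spec.body_mean_hu + body_field[body]

    masks: list[ROIMask] = []
    for roi in spec.rois:
        m = _ellipsoid_mask(shape, spacing, origin, roi.center, roi.radii)
        if not np.all(body[m]):
            raise ValueError(f"ROI {roi.name!r} extends outside the body region")
        field_r = _correlated_field(
            rng, shape, spacing, roi.correlation_length, roi.texture_amplitude
        )
        values[m] = roi.mean_hu + field_r[m]
        masks.append(ROIMask(mask=m, name=roi.name, tissue_class=roi.tissue_class))

    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if np.any(masks[i].mask & masks[j].mask):
                raise ValueError(
                    f"ROIs {masks[i].name!r} and {masks[j].name!r} overlap"
                )

    # Gaussian tails may exceed the printable contrast range; clamp.
    np.clip(values, HU_MIN, HU_MAX, out=values)
    return VoxelVolume(values, spacing, origin), masks


# ----------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    # NIfTI maps index -> position of the voxel; under the voxel-center
    # convention index 0 sits at origin + spacing/2.
    aff[:3, 3] = [o + 0.5 * s for o, s in zip(origin, spacing)]
    return aff


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(
        volume.values.astype(np.float64), _affine(volume.spacing, volume.origin)
    )
    nib.save(img, str(path))


def read_volume(path: str | Path) -> VoxelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D NIfTI data, got {data.ndim}D")
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, a])) for a in range(3))
    origin = tuple(float(aff[a, 3] - 0.5 * spacing[a]) for a in range(3))
    return VoxelVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def write_mask(mask: ROIMask, volume: VoxelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(
        mask.mask.astype(np.uint8), _affine(volume.spacing, volume.origin)
    )
    img.header["descrip"] = mask.tissue_class.encode()
    nib.save(img, str(path))


def read_mask(
    path: str | Path,
    volume: VoxelVolume,
    name: str | None = None,
    tissue_class: str | None = None,
) -> ROIMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D NIfTI mask, got {data.ndim}D")
    if data.shape != volume.shape:
        raise ValueError(
            f"mask shape {data.shape} not congruent with volume {volume.shape}"
        )
    if tissue_class is None:
        descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
        tissue_class = descrip if descrip in TISSUE_CLASSES else "normal_liver"
    if name is None:
        name = path.name.split(".")[0]
    mask = data != 0
    if not mask.any():
        raise ValueError(f"empty ROI in {path}")
    return ROIMask(mask=mask, name=name, tissue_class=tissue_class)
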