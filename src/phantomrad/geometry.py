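"""Explicit-vector helical cone-beam scan geometries.

Each view is described by four 3-vectors (source position, detector center,
detector column axis, detector row axis — the axes scaled by the pixel
pitch), the same 12-component convention used by explicit-vector cone-beam
toolkits.  The default geometry places the source 500 mm and the detector
1000 mm from/through the rotation axis (magnification 2) with a flat square
512 x 512 detector of 1 mm pixels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

DEFAULT_DETECTOR = (512, 512, 1.0)  # rows, cols, pixel pitch (mm)
DEFAULT_SOD = 500.0  # source-to-isocenter distance (mm)
DEFAULT_SDD = 1000.0  # source-to-detector distance (mm)


@dataclass
class ProjectionGeometry:
    """Per-view source/detector pose vectors of a cone-beam scan."""

    src: np.ndarray  # (n, 3) source positions, mm
    det_center: np.ndarray  # (n, 3) detector centers, mm
    det_u: np.ndarray  # (n, 3) column axis scaled by pixel pitch, mm
    det_v: np.ndarray  # (n, 3) row axis scaled by pixel pitch, mm
    det_shape: tuple[int, int]  # (rows, cols)
    source_to_isocenter: float
    source_to_detector: float
    pitch: float = 1.0

    def __post_init__(self) -> None:
        for name in ("src", "det_center", "det_u", "det_v"):
            setattr(self, name, np.atleast_2d(np.asarray(getattr(self, name), float)))
        n = self.src.shape[0]
        if n < 1:
            raise ValueError("geometry must contain at least one projection view")
        for name in ("det_center", "det_u", "det_v"):
            if getattr(self, name).shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")
        if not (self.source_to_detector > self.source_to_isocenter > 0):
            raise ValueError(
                "require source_to_detector > source_to_isocenter > 0, got "
                f"{self.source_to_detector} / {self.source_to_isocenter}"
            )
        dots = np.abs(np.sum(self.det_u * self.det_v, axis=1))
        if np.any(dots > 1e-9 * self.pixel_pitch**2):
            raise ValueError("detector axes must be orthogonal in every view")
        if not np.allclose(
            np.linalg.norm(self.det_u, axis=1),
            np.linalg.norm(self.det_v, axis=1),
            rtol=1e-9,
        ):
            raise ValueError("detector pixels must be square")

    @property
    def n_projections(self) -> int:
        return self.src.shape[0]

    @property
    def pixel_pitch(self) -> float:
        return float(np.linalg.norm(self.det_u[0]))

    def pixel_positions(self, view: int) -> np.ndarray:
        """World positions of all detector pixel centers for one view,
        shaped (rows, cols, 3)."""
        rows, cols = self.det_shape
        r = np.arange(rows) - (rows - 1) / 2.0
        c = np.arange(cols) - (cols - 1) / 2.0
        return (
            self.det_center[view]
            + c[None, :, None] * self.det_u[view]
            + r[:, None, None] * self.det_v[view]
        )

    # ------------------------------------------------------------------
    def to_vectors(self) -> np.ndarray:
        """(n, 12) array [src, det_center, u, v] per view."""
        return np.hstack([self.src, self.det_center, self.det_u, self.det_v])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "vectors": self.to_vectors().tolist(),
            "det_shape": list(self.det_shape),
            "source_to_isocenter": self.source_to_isocenter,
            "source_to_detector": self.source_to_detector,
            "pitch": self.pitch,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProjectionGeometry":
        payload = json.loads(Path(path).read_text())
        vec = np.asarray(payload["vectors"], dtype=float)
        return cls(
            src=vec[:, 0:3],
            det_center=vec[:, 3:6],
            det_u=vec[:, 6:9],
            det_v=vec[:, 9:12],
            det_shape=tuple(payload["det_shape"]),
            source_to_isocenter=payload["source_to_isocenter"],
            source_to_detector=payload["source_to_detector"],
            pitch=payload["pitch"],
        )

    def cache_key(self) -> tuple:
        return (
            self.det_shape,
            self.src.shape[0],
            round(self.source_to_isocenter, 9),
            round(self.source_to_detector, 9),
            round(self.pitch, 9),
            hash(self.to_vectors().tobytes()),
        )


def rotation_advance(
    detector: tuple[int, int, float] = DEFAULT_DETECTOR,
    sod: float = DEFAULT_SOD,
    sdd: float = DEFAULT_SDD,
    pitch: float = 1.0,
) -> float:
    """Source z advance per full rotation: pitch x detector height
    projected to the isocenter plane."""
    rows, _, pixel = detector
    return pitch * rows * pixel * (sod / sdd)


def build_helical_geometry(
    n_projections: int,
    z_start: float,
    z_end: float,
    detector: tuple[int, int, float] = DEFAULT_DETECTOR,
    sod: float = DEFAULT_SOD,
    sdd: float = DEFAULT_SDD,
    pitch: float = 1.0,
    angle_start: float = 0.0,
) -> ProjectionGeometry:
    """Helical scan with views uniform in gantry angle.

    The number of full rotations is the smallest integer covering the
    requested z range at the given pitch; the source z advances linearly
    in angle.  ``z_start == z_end`` yields a single circular rotation.
    """
    if n_projections < 1:
        raise ValueError("n_projections must be >= 1")
    if z_end < z_start:
        raise ValueError("z_end must be >= z_start")
    rows, cols, pixel = detector
    advance = rotation_advance(detector, sod, sdd, pitch)

    if z_end > z_start and advance <= 0:
        warnings.warn(
            f"zero table advance (pitch {pitch}): requested z range "
            f"[{z_start}, {z_end}] covered only at z={z_start}",
            stacklevel=2,
        )
        n_rot = 1
        advance = 0.0
    elif z_end > z_start:
        n_rot = int(np.ceil((z_end - z_start) / advance))
    else:
        n_rot = 1
        advance = 0.0

    angles = angle_start + np.linspace(
        0.0, 2.0 * np.pi * n_rot, n_projections, endpoint=False
    )
    z = z_start + (angles - angle_start) / (2.0 * np.pi) * advance

    cos, sin = np.cos(angles), np.sin(angles)
    src = np.stack([-sod * cos, -sod * sin, z], axis=1)
    det_center = np.stack([(sdd - sod) * cos, (sdd - sod) * sin, z], axis=1)
    det_u = pixel * np.stack([-sin, cos, np.zeros_like(angles)], axis=1)
    det_v = pixel * np.stack(
        [np.zeros_like(angles), np.zeros_like(angles), np.ones_like(angles)], axis=1
    )
    return ProjectionGeometry(
        src=src,
        det_center=det_center,
        det_u=det_u,
        det_v=det_v,
        det_shape=(rows, cols),
        source_to_isocenter=sod,
        source_to_detector=sdd,
        pitch=pitch if advance > 0 else 0.0,
    )


def build_circular_geometry(
    n_projections: int,
    z: float = 0.0,
    detector: tuple[int, int, float] = DEFAULT_DETECTOR,
    sod: float = DEFAULT_SOD,
    sdd: float = DEFAULT_SDD,
    angle_start: float = 0.0,
) -> ProjectionGeometry:
    """Single-rotation circular trajectory (pitch 0) at a fixed z."""
    return build_helical_geometry(
        n_projections,
        z_start=z,
        z_end=z,
        detector=detector,
        sod=sod,
        sdd=sdd,
        pitch=0.0,
        angle_start=angle_start,
    )


def build_fan_geometry(
    n_projections: int,
    n_detectors: int = 96,
    pixel: float = 2.0,
    sod: float = DEFAULT_SOD,
    sdd: float = DEFAULT_SDD,
    z: float = 0.0,
    angle_start: float = 0.0,
) -> ProjectionGeometry:
    """2D fast mode: a single-row detector on a circular trajectory,
    equivalent to a fan-beam scan of one slice."""
    return build_circular_geometry(
        n_projections,
        z=z,
        detector=(1, n_detectors, pixel),
        sod=sod,
        sdd=sdd,
        angle_start=angle_start,
    )
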