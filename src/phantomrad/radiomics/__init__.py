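"""Radiomics feature extraction: 86 features from a volume-restricted ROI.

Families and counts: 18 first-order, 22 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM
(see :mod:`phantomrad.radiomics.manifest`).  Extraction uses fixed
bin-width discretisation (default 25 HU), neighbour distance 1, a
symmetric aggregated GLCM, dependence tolerance 0, and no normalisation,
resampling or resegmentation.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np

from phantomrad.phantom import ROIMask, VoxelVolume
from phantomrad.radiomics.discretise import DiscretisedROI, discretise
from phantomrad.radiomics.firstorder import first_order_features
from phantomrad.radiomics.manifest import (
    CANONICAL_NAMES,
    FAMILIES,
    FAMILY_COUNTS,
    N_FEATURES,
    family_of,
)
from phantomrad.radiomics.matrices import (
    OFFSETS_13,
    glcm_matrix,
    gldm_matrix,
    glrlm_matrix,
    glszm_matrix,
)
from phantomrad.radiomics.texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_NAMES",
    "DiscretisedROI",
    "ExtractionConfig",
    "FAMILIES",
    "FAMILY_COUNTS",
    "FeatureVector",
    "N_FEATURES",
    "OFFSETS_13",
    "discretise",
    "extract_features",
    "family_of",
    "first_order_features",
    "glcm_features",
    "glcm_matrix",
    "gldm_features",
    "gldm_matrix",
    "glrlm_features",
    "glrlm_matrix",
    "glszm_features",
    "glszm_matrix",
]


@dataclass
class ExtractionConfig:
    """Extraction settings; defaults replicate the study configuration."""

    bin_width: float = 25.0
    neighbor_distance: int = 1
    glcm_symmetric: bool = True
    gldm_alpha: float = 0.0
    voxel_array_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.neighbor_distance < 1:
            raise ValueError("neighbor_distance must be >= 1")
        if not self.glcm_symmetric:
            raise ValueError("only the symmetric GLCM variant is provided")


@dataclass
class FeatureVector:
    """Ordered map of the 86 features for one (acquisition, ROI) pair."""

    values: "OrderedDict[str, float]"
    acquisition_id: str = ""
    roi_name: str = ""
    tissue_class: str = ""

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != CANONICAL_NAMES:
            raise ValueError(
                f"feature vector must hold exactly the {N_FEATURES} canonical "
                "features in canonical order"
            )

    def __len__(self) -> int:
        return len(self.values)

    def as_row(self) -> dict:
        row = {
            "acquisition_id": self.acquisition_id,
            "roi": self.roi_name,
            "tissue_class": self.tissue_class,
        }
        row.update(self.values)
        return row


def extract_features(
    volume: VoxelVolume,
    mask: ROIMask | np.ndarray,
    config: ExtractionConfig | None = None,
    acquisition_id: str = "",
) -> FeatureVector:
    """Extract all 86 features from ``volume`` restricted to ``mask``."""
    config = config or ExtractionConfig()
    if isinstance(mask, ROIMask):
        mask_arr = mask.mask
        roi_name = mask.name
        tissue_class = mask.tissue_class
    else:
        mask_arr = np.asarray(mask).astype(bool)
        roi_name = ""
        tissue_class = ""
    if mask_arr.shape != volume.shape:
        raise ValueError("mask not congruent with volume")

    disc = discretise(volume.values, mask_arr, config.bin_width)
    if disc.n_levels == 1:
        logger.warning(
            "ROI %r has a single grey level; degenerate texture features "
            "return 0 by convention",
            roi_name,
        )

    fo = first_order_features(
        volume.values,
        mask_arr,
        spacing=volume.spacing,
        bin_width=config.bin_width,
        voxel_array_shift=config.voxel_array_shift,
    )
    glcm = glcm_features(glcm_matrix(disc, distance=config.neighbor_distance))
    gldm = gldm_features(
        gldm_matrix(disc, alpha=config.gldm_alpha, distance=config.neighbor_distance)
    )
    glrlm = glrlm_features(
        glrlm_matrix(disc), n_voxels=disc.n_voxels, n_directions=len(OFFSETS_13)
    )
    glszm = glszm_features(glszm_matrix(disc), n_voxels=disc.n_voxels)

    by_family = {
        "firstorder": fo,
        "glcm": glcm,
        "gldm": gldm,
        "glrlm": glrlm,
        "glszm": glszm,
    }
    values: "OrderedDict[str, float]" = OrderedDict()
    for family, names in FAMILIES:
        fam_values = by_family[family]
        for name in names:
            values[f"{family}_{name}"] = float(fam_values[name])
    return FeatureVector(
        values=values,
        acquisition_id=acquisition_id,
        roi_name=roi_name,
        tissue_class=tissue_class,
    )
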