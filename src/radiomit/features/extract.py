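"""Feature extraction orchestration across families."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from radiomit.features.discretize import discretize
from radiomit.features.firstorder import (
    DEFAULT_FRACTIONS,
    histogram_features,
    intensity_features,
    morphology_features,
    volumetric_features,
)
from radiomit.features.resample import offset_to_voxels
from radiomit.features.texture import glrlm_features, glszm_features, ngtdm_features
from radiomit.types import FeatureTable, VoxelImage

__all__ = ["ExtractionParams", "DEFAULT_FAMILIES", "extract_features", "extract_table"]

DEFAULT_FAMILIES = (
    "intensity",
    "histogram",
    "volumetric",
    "morphology",
    "glrlm",
    "ngtdm",
    "glszm",
)

TEXTURE_FAMILIES = frozenset({"glrlm", "ngtdm", "glszm"})
_MIN_TEXTURE_ROI = 10


@dataclass
class ExtractionParams:
    """Extraction configuration.

    ``offset_mm`` sets the physical neighbor distance; it controls the NGTDM
    neighborhood (per-axis voxel distance via ``offset_to_voxels``) and, when
    ``offset_glrlm_stride`` is set, the GLRLM direction stride.
    """

    offset_mm: float = 3.0
    n_bins: int = 32
    families: tuple[str, ...] = DEFAULT_FAMILIES
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    glszm_connectivity: int = 26
    offset_glrlm_stride: bool = False

    def __post_init__(self) -> None:
        if self.offset_mm <= 0:
            raise ValueError("offset_mm must be > 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        unknown = set(self.families) - set(DEFAULT_FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")


def extract_features(
    image: VoxelImage, params: ExtractionParams | None = None
) -> dict[str, float]:
    """Extract the requested families from one image; returns name -> value.

    ROIs below 10 voxels skip the texture families with a warning.
    """
    params = params or ExtractionParams()
    out: dict[str, float] = {}
    roi_size = int(image.mask.sum())

    families = list(params.families)
    if roi_size < _MIN_TEXTURE_ROI and TEXTURE_FAMILIES & set(families):
        warnings.warn(
            f"ROI has {roi_size} voxels (< {_MIN_TEXTURE_ROI}); skipping texture families",
            stacklevel=2,
        )
        families = [f for f in families if f not in TEXTURE_FAMILIES]

    needs_levels = {"histogram", "glrlm", "ngtdm", "glszm"} & set(families)
    levels = discretize(image, params.n_bins) if needs_levels else None

    if "intensity" in families:
        out.update(intensity_features(image.intensities, image.mask))
    if "histogram" in families:
        out.update(histogram_features(levels, image.mask, params.n_bins))
    if "volumetric" in families:
        out.update(volumetric_features(image.intensities, image.mask, params.fractions))
    if "morphology" in families:
        out.update(morphology_features(image.mask, image.spacing))
    if "glrlm" in families:
        distance = offset_to_voxels(params.offset_mm, image.spacing)
        stride = max(distance) if params.offset_glrlm_stride else 1
        out.update(glrlm_features(levels, image.mask, stride=stride))
    if "ngtdm" in families:
        distance = offset_to_voxels(params.offset_mm, image.spacing)
        out.update(ngtdm_features(levels, image.mask, distance=distance))
    if "glszm" in families:
        out.update(
            glszm_features(levels, image.mask, connectivity=params.glszm_connectivity)
        )
    return out


def feature_family(name: str) -> str:
    """Family tag from a feature name prefix."""
    prefix = name.split("_", 1)[0]
    return {
        "intensity": "intensity",
        "hist": "histogram",
        "vol": "volumetric",
        "morph": "morphology",
        "glrlm": "glrlm",
        "ngtdm": "ngtdm",
        "glszm": "glszm",
    }[prefix]


def extract_table(
    images: list[VoxelImage],
    patient_ids: list[str],
    params: ExtractionParams | None = None,
) -> FeatureTable:
    """Extract a FeatureTable for a cohort of images."""
    if len(images) != len(patient_ids):
        raise ValueError("images and patient_ids length mismatch")
    rows = [extract_features(img, params) for img in images]
    df = pd.DataFrame(rows, index=list(patient_ids))
    families = {name: feature_family(name) for name in df.columns}
    return FeatureTable(df, families)
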