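"""Anisotropic resampling and physical-unit neighborhood offsets."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from radiomit.types import VoxelImage

__all__ = ["compute_min_spacing", "resample_image", "offset_to_voxels"]


def compute_min_spacing(images: list[VoxelImage]) -> tuple[float, float, float]:
    """Per-axis minimum voxel spacing over a dataset.

    This is the resampling target for the minimum-voxel-spacing scenario:
    each axis takes the smallest spacing observed on that axis across all
    images (the minima may come from different images).
    """
    if not images:
        raise ValueError("compute_min_spacing: empty image list")
    spacings = np.array([img.spacing for img in images], dtype=float)
    return tuple(spacings.min(axis=0))


def resample_image(
    image: VoxelImage, target_spacing: tuple[float, float, float]
) -> VoxelImage:
    """Resample to ``target_spacing`` (trilinear intensities, nearest mask).

    The output grid keeps the origin at the first voxel centre and covers the
    source physical extent; sample ``j`` on an axis sits at physical position
    ``j * target`` and is interpolated at source coordinate
    ``j * target / source``. Raises if a target spacing exceeds the physical
    extent of its axis (nothing to sample).
    """
    target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    shape = image.intensities.shape
    extent = [(n - 1) * s for n, s in zip(shape, image.spacing)]
    for axis, (t, e) in enumerate(zip(target, extent)):
        if e > 0 and t > e:
            raise ValueError(
                f"target spacing {t} mm on axis {axis} coarser than image extent {e} mm"
            )

    new_shape = tuple(
        int(np.floor(e / t + 1e-9)) + 1 for e, t in zip(extent, target)
    )
    coords = np.meshgrid(
        *[
            np.arange(n_new) * t / s
            for n_new, t, s in zip(new_shape, target, image.spacing)
        ],
        indexing="ij",
    )
    coords = np.stack(coords)
    intensities = ndimage.map_coordinates(
        image.intensities, coords, order=1, mode="nearest"
    )
    mask = ndimage.map_coordinates(
        image.mask.astype(np.uint8), coords, order=0, mode="nearest"
    ).astype(bool)
    if not mask.any():
        # coarse grids can miss a thin ROI entirely; keep the nearest voxel
        centroid = np.array(np.nonzero(image.mask)).mean(axis=1)
        idx = tuple(
            int(round(c * s / t)) for c, s, t in zip(centroid, image.spacing, target)
        )
        idx = tuple(min(i, n - 1) for i, n in zip(idx, new_shape))
        mask = np.zeros(new_shape, dtype=bool)
        mask[idx] = True
    return VoxelImage(intensities, target, mask)


def offset_to_voxels(
    offset_mm: float, spacing: tuple[float, float, float]
) -> tuple[int, int, int]:
    """Convert a physical neighbor offset to per-axis voxel distances.

    Nearest-integer rounding (half up), clamped to a minimum of 1 so that a
    coarse axis still has a neighborhood.
    """
    if offset_mm <= 0:
        raise ValueError("offset_mm must be positive")
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    return tuple(
        max(1, int(np.floor(offset_mm / s + 0.5))) for s in spacing
    )
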