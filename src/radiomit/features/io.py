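"""NIfTI image/mask I/O."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from radiomit.types import VoxelImage

__all__ = ["load_nifti_pair", "save_nifti_pair"]


def load_nifti_pair(image_path, mask_path) -> VoxelImage:
    """Load an image + binary mask NIfTI pair as a VoxelImage."""
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(msk.dataobj) > 0.5
    return VoxelImage(data, spacing, mask)


def save_nifti_pair(image: VoxelImage, image_path, mask_path) -> None:
    """Write a VoxelImage as an image + mask NIfTI pair (spacing in affine)."""
    affine = np.diag([*image.spacing, 1.0])
    for path, data in (
        (image_path, image.intensities.astype(np.float32)),
        (mask_path, image.mask.astype(np.uint8)),
    ):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(data, affine), str(path))
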