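"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class VoxelImage:
    """A 3D scalar image with physical voxel spacing and a binary ROI mask.

    Attributes
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Scalar intensity volume.
    spacing : tuple of float
        Physical voxel size (x, y, z) in millimetres; strictly positive.
    mask : ndarray of bool, same shape as ``intensities``
        ROI membership; must contain at least one foreground voxel.

    Voxel indices are 0-based and the physical position of voxel ``(i, j, k)``
    is ``(i*sx, j*sy, k*sz)`` (origin at the first voxel centre).
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if self.intensities.shape != self.mask.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != intensity shape {self.intensities.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        if not self.mask.any():
            raise ValueError("mask has no foreground voxel")

    @property
    def roi_values(self) -> np.ndarray:
        """Intensities of ROI voxels as a flat array."""
        return self.intensities[self.mask]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class FeatureTable:
    """Patients x features numeric matrix with per-feature family labels."""

    values: pd.DataFrame  # index: patient_id, columns: feature names
    families: dict[str, str] = field(default_factory=dict)  # feature -> family

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        missing = set(self.families) - set(self.values.columns)
        if missing:
            raise ValueError(f"family labels for unknown features: {sorted(missing)}")

    @property
    def patients(self) -> list:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def subset_features(self, names) -> "FeatureTable":
        names = list(names)
        return FeatureTable(
            self.values[names].copy(),
            {k: v for k, v in self.families.items() if k in names},
        )

    def subset_patients(self, ids) -> "FeatureTable":
        return FeatureTable(self.values.loc[list(ids)].copy(), dict(self.families))

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="patient_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="patient_id")
        return cls(df)


@dataclass
class CohortTable:
    """Per-patient batch variables, clinical covariates and survival outcome.

    ``data`` is indexed by patient_id. ``batch_variables`` and ``covariates``
    name the columns playing those roles; ``time_col``/``event_col`` name the
    survival outcome when present.
    """

    data: pd.DataFrame
    batch_variables: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    time_col: str | None = None
    event_col: str | None = None

    def __post_init__(self) -> None:
        for col in [*self.batch_variables, *self.covariates]:
            if col not in self.data.columns:
                raise ValueError(f"column {col!r} missing from cohort table")
        for col in (self.time_col, self.event_col):
            if col is not None and col not in self.data.columns:
                raise ValueError(f"column {col!r} missing from cohort table")

    @property
    def patients(self) -> list:
        return list(self.data.index)

    def batch(self, name: str) -> pd.Series:
        if name not in self.batch_variables:
            raise KeyError(f"{name!r} is not a batch variable ({self.batch_variables})")
        return self.data[name]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="patient_id")
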