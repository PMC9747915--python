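"""Synthetic cohorts with planted batch effects, phenotypes and outcomes.

The feature-table generator follows the location/scale batch-effect model the
harmonizer assumes: entry (patient i, feature g) is

    base_mean[g] + covariate_term(i, g) + phenotype_shift(i, g)
        + gamma[g, batch(i)] + delta[g, batch(i)] * eps,   eps ~ N(0, 1)

so ordinary least squares on batch indicators recovers the planted gamma and
empirical-Bayes harmonization has a well-specified target. The image generator
plants acquisition heterogeneity (spacing, smoothing kernel, intensity offset)
on top of a phenotype-dependent textured ellipsoid; survival times are
exponential with proportional hazards and independent exponential censoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from radiomit.types import CohortTable, FeatureTable, VoxelImage

__all__ = [
    "BatchVariable",
    "BatchDesign",
    "PhenotypeDesign",
    "SurvivalDesign",
    "simulate_feature_table",
    "simulate_images",
    "simulate_survival",
]


@dataclass
class BatchVariable:
    """One batch variable: its levels and per-patient assignment probabilities.

    ``conditional_on``/``probs_by_level`` optionally make the assignment
    probabilities depend on the level of an earlier batch variable (used to
    plant batch-batch confounding).
    """

    name: str
    levels: list[str]
    probs: list[float]
    conditional_on: str | None = None
    probs_by_level: dict[str, list[float]] | None = None

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.probs):
            raise ValueError(f"{self.name}: levels/probs length mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: assignment probabilities must sum to 1")
        if any(p < 0 for p in self.probs):
            raise ValueError(f"{self.name}: negative probability")
        if (self.conditional_on is None) != (self.probs_by_level is None):
            raise ValueError(f"{self.name}: conditional_on and probs_by_level go together")
        if self.probs_by_level is not None:
            for level, probs in self.probs_by_level.items():
                if len(probs) != len(self.levels) or abs(sum(probs) - 1.0) > 1e-9:
                    raise ValueError(f"{self.name}: bad conditional probs for {level!r}")


@dataclass
class BatchDesign:
    """Planted additive (gamma) and multiplicative (delta) batch effects.

    ``gamma[var][level]`` / ``delta[var][level]`` give the per-feature shift and
    scale for that level, either a scalar (applied to all features) or an array
    of length n_features. delta must be strictly positive.
    ``phenotype_association`` optionally tilts the assignment of a two-level
    batch variable by phenotype class (odds ratio knob for confounding
    experiments): for class c > 0 the odds of the second level are multiplied
    by ``odds_ratio ** c``.
    """

    variables: list[BatchVariable] = field(default_factory=list)
    gamma: dict[str, dict[str, object]] = field(default_factory=dict)
    delta: dict[str, dict[str, object]] = field(default_factory=dict)
    phenotype_association: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate batch variable names")
        for var, levels in self.delta.items():
            for level, value in levels.items():
                if np.any(np.asarray(value, dtype=float) <= 0):
                    raise ValueError(f"delta must be > 0 ({var}={level})")

    def _effect(self, table: dict, var: str, level: str, n_features: int) -> np.ndarray:
        default = 0.0 if table is self.gamma else 1.0
        value = table.get(var, {}).get(level, default)
        return np.broadcast_to(np.asarray(value, dtype=float), (n_features,))

    def gamma_for(self, var: str, level: str, n_features: int) -> np.ndarray:
        return self._effect(self.gamma, var, level, n_features)

    def delta_for(self, var: str, level: str, n_features: int) -> np.ndarray:
        return self._effect(self.delta, var, level, n_features)


@dataclass
class PhenotypeDesign:
    """Latent phenotype classes carried by a subset of features."""

    n_classes: int = 2
    class_proportions: list[float] | None = None
    effect_size: float = 1.5  # mean shift per affected feature, in SD units
    affected_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.class_proportions is None:
            self.class_proportions = [1.0 / self.n_classes] * self.n_classes
        if len(self.class_proportions) != self.n_classes:
            raise ValueError("class_proportions length != n_classes")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must lie in [0, 1]")


@dataclass
class SurvivalDesign:
    """Exponential event and censoring processes under proportional hazards."""

    baseline_rate: float = 0.1
    log_hazard_ratios: dict[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")


def _assign_batches(
    rng: np.random.Generator,
    design: BatchDesign,
    phenotype: np.ndarray,
) -> pd.DataFrame:
    n = len(phenotype)
    cols = {}
    for var in design.variables:
        odds_ratio = design.phenotype_association.get(var.name)
        if var.conditional_on is not None:
            if var.conditional_on not in cols:
                raise ValueError(
                    f"{var.name}: conditional on {var.conditional_on!r}, "
                    "which must be listed earlier"
                )
            parent = cols[var.conditional_on]
            uncovered = set(np.unique(parent)) - set(var.probs_by_level)
            if uncovered:
                raise ValueError(f"{var.name}: no conditional probs for {sorted(uncovered)}")
            idx = np.empty(n, dtype=int)
            for level, probs in var.probs_by_level.items():
                rows = parent == level
                idx[rows] = rng.choice(len(var.levels), size=int(rows.sum()), p=probs)
        elif odds_ratio is None:
            idx = rng.choice(len(var.levels), size=n, p=var.probs)
        else:
            if len(var.levels) != 2:
                raise ValueError("phenotype_association requires a two-level variable")
            p1 = np.asarray(var.probs[1], dtype=float)
            odds = p1 / (1 - p1) * np.power(odds_ratio, phenotype)
            p1_cond = odds / (1 + odds)
            idx = (rng.random(n) < p1_cond).astype(int)
        cols[var.name] = np.asarray(var.levels)[idx]
    return pd.DataFrame(cols)


def simulate_feature_table(
    n_patients: int,
    n_features: int,
    batch: BatchDesign,
    phenotype: PhenotypeDesign,
    covariate_effects: np.ndarray | float = 0.0,
    seed: int = 0,
    base_mean: float = 0.0,
) -> tuple[FeatureTable, CohortTable]:
    """Simulate a feature table under the location/scale batch-effect model.

    Returns the feature table and a cohort table holding batch assignments,
    the true phenotype label, and one standard-normal clinical covariate
    (column ``covar``) whose per-feature slopes are ``covariate_effects``.

    Raises ``ValueError`` if any batch level receives fewer than 2 patients
    (per-level variance estimation would be undefined downstream).
    """
    rng = np.random.default_rng(seed)
    pheno = rng.choice(phenotype.n_classes, size=n_patients, p=phenotype.class_proportions)
    assignments = _assign_batches(rng, batch, pheno)

    for var in batch.variables:
        counts = pd.Series(assignments[var.name]).value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"batch variable {var.name!r}: level(s) {list(small.index)} have < 2 patients"
            )

    covar = rng.standard_normal(n_patients)
    slopes = np.broadcast_to(np.asarray(covariate_effects, dtype=float), (n_features,))

    n_affected = int(round(phenotype.affected_fraction * n_features))
    affected = np.zeros(n_features, dtype=bool)
    affected[:n_affected] = True

    # class shifts spread classes symmetrically around 0 on affected features
    class_shift = (np.arange(phenotype.n_classes) - (phenotype.n_classes - 1) / 2.0)
    class_shift = class_shift * phenotype.effect_size

    x = base_mean + np.outer(covar, slopes)
    x = x + np.outer(class_shift[pheno], affected.astype(float))

    noise = rng.standard_normal((n_patients, n_features))
    gamma_total = np.zeros((n_patients, n_features))
    delta_total = np.ones((n_patients, n_features))
    for var in batch.variables:
        for level in var.levels:
            rows = assignments[var.name].to_numpy() == level
            gamma_total[rows] += batch.gamma_for(var.name, level, n_features)
            delta_total[rows] *= batch.delta_for(var.name, level, n_features)
    x = x + gamma_total + delta_total * noise

    ids = [f"P{i:04d}" for i in range(n_patients)]
    features = pd.DataFrame(x, index=ids, columns=[f"f{g:03d}" for g in range(n_features)])
    cohort = assignments.copy()
    cohort.index = ids
    cohort["phenotype"] = pheno
    cohort["covar"] = covar
    cohort.attrs["affected_features"] = [f"f{g:03d}" for g in np.flatnonzero(affected)]
    return (
        FeatureTable(features),
        CohortTable(
            cohort,
            batch_variables=[v.name for v in batch.variables],
            covariates=["covar"],
        ),
    )


def _textured_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    correlation_mm: float,
    amplitude: float,
) -> np.ndarray:
    """Spatially correlated Gaussian noise with a physical correlation length."""
    white = rng.standard_normal(shape)
    sigma_vox = [max(correlation_mm / s, 1e-6) for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return amplitude * smooth


def simulate_images(
    n_patients: int,
    base_shape: tuple[int, int, int] = (40, 40, 40),
    spacing_by_batch: dict[str, tuple[float, float, float]] | None = None,
    kernel_sigma_by_batch: dict[str, float] | None = None,
    contrast_shift_by_batch: dict[str, float] | None = None,
    phenotype: PhenotypeDesign | None = None,
    seed: int = 0,
    semi_axes_mm: tuple[float, float, float] | None = None,
    correlation_mm_by_class: tuple[float, ...] = (0.8, 2.4),
    texture_amplitude: float = 60.0,
    noise_sd: float = 5.0,
) -> tuple[list[VoxelImage], CohortTable]:
    """Render synthetic tumor volumes with planted acquisition heterogeneity.

    Each patient gets an ellipsoidal ROI filled with textured noise whose
    correlation length depends on the phenotype class (coarser texture for
    higher classes), smoothed with a batch-specific kernel, shifted by a
    batch-specific contrast offset, on a batch-specific voxel grid.

    Batch levels for the three image batch variables (``spacing``, ``kernel``,
    ``contrast``) are drawn uniformly over the keys of the corresponding
    mapping. Raises ``ValueError`` for degenerate ellipsoids (< 2 voxels on
    any semi-axis).
    """
    phenotype = phenotype or PhenotypeDesign()
    spacing_by_batch = spacing_by_batch or {"iso1": (1.0, 1.0, 1.0)}
    kernel_sigma_by_batch = kernel_sigma_by_batch or {"soft": 0.0}
    contrast_shift_by_batch = contrast_shift_by_batch or {"nc": 0.0}

    rng = np.random.default_rng(seed)
    pheno = rng.choice(phenotype.n_classes, size=n_patients, p=phenotype.class_proportions)
    if len(correlation_mm_by_class) < phenotype.n_classes:
        raise ValueError("need one correlation length per phenotype class")

    spacing_levels = sorted(spacing_by_batch)
    kernel_levels = sorted(kernel_sigma_by_batch)
    contrast_levels = sorted(contrast_shift_by_batch)

    images: list[VoxelImage] = []
    rows = []
    for i in range(n_patients):
        sp_level = spacing_levels[rng.integers(len(spacing_levels))]
        k_level = kernel_levels[rng.integers(len(kernel_levels))]
        c_level = contrast_levels[rng.integers(len(contrast_levels))]
        spacing = tuple(float(s) for s in spacing_by_batch[sp_level])
        if any(s <= 0 for s in spacing):
            raise ValueError("spacings must be strictly positive")

        shape = tuple(int(s) for s in base_shape)
        extent = [(n - 1) * s for n, s in zip(shape, spacing)]
        if semi_axes_mm is None:
            axes_mm = tuple(0.32 * e for e in extent)
        else:
            axes_mm = semi_axes_mm
        axes_vox = [a / s for a, s in zip(axes_mm, spacing)]
        if any(a < 2 for a in axes_vox):
            raise ValueError(
                f"degenerate ellipsoid: semi-axes {axes_vox} voxels (need >= 2)"
            )

        centre = [(n - 1) / 2.0 for n in shape]
        grid = np.indices(shape, dtype=float)
        dist2 = sum(
            ((grid[d] - centre[d]) / axes_vox[d]) ** 2 for d in range(3)
        )
        mask = dist2 <= 1.0
        if mask.sum() < 50:
            raise ValueError("ROI smaller than 50 voxels; enlarge base_shape or axes")

        corr = correlation_mm_by_class[pheno[i]]
        img = 100.0 + _textured_field(rng, shape, spacing, corr, texture_amplitude)
        img += noise_sd * rng.standard_normal(shape)

        sigma_mm = float(kernel_sigma_by_batch[k_level])
        if sigma_mm > 0:
            img = ndimage.gaussian_filter(img, sigma=[sigma_mm / s for s in spacing])
        img = img + float(contrast_shift_by_batch[c_level])

        images.append(VoxelImage(img, spacing, mask))
        rows.append(
            {
                "spacing": sp_level,
                "kernel": k_level,
                "contrast": c_level,
                "spacing_x": spacing[0],
                "spacing_y": spacing[1],
                "spacing_z": spacing[2],
                "phenotype": int(pheno[i]),
            }
        )

    ids = [f"P{i:04d}" for i in range(n_patients)]
    cohort = pd.DataFrame(rows, index=ids)
    cohort["covar"] = rng.standard_normal(n_patients)
    return images, CohortTable(
        cohort,
        batch_variables=["spacing", "kernel", "contrast"],
        covariates=["covar"],
    )


def simulate_survival(
    cohort: CohortTable,
    design: SurvivalDesign,
    seed: int = 0,
) -> CohortTable:
    """Fill survival ``time``/``event`` columns by proportional-hazards sampling.

    The linear predictor sums ``log_hazard_ratios[name] * column`` over the
    named cohort columns (``phenotype`` enters as its numeric label). Latent
    event times are exponential with rate ``baseline_rate * exp(lp)``;
    censoring is an independent exponential; observed time is the minimum.
    """
    rng = np.random.default_rng(seed)
    df = cohort.data.copy()
    n = len(df)
    lp = np.zeros(n)
    for name, beta in design.log_hazard_ratios.items():
        if name not in df.columns:
            raise ValueError(f"log-hazard covariate {name!r} not in cohort table")
        lp += beta * df[name].to_numpy(dtype=float)

    event_time = rng.exponential(1.0, size=n) / (design.baseline_rate * np.exp(lp))
    if design.censoring_rate > 0:
        cens_time = rng.exponential(1.0 / design.censoring_rate, size=n)
    else:
        cens_time = np.full(n, np.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)

    df["time"] = time
    df["event"] = event
    out = CohortTable(
        df,
        batch_variables=list(cohort.batch_variables),
        covariates=list(cohort.covariates),
        time_col="time",
        event_col="event",
    )
    out.data.attrs.update(cohort.data.attrs)
    if event.sum() == 0:
        warnings.warn("simulated cohort has no events (all censored)", stacklevel=2)
        out.data.attrs["all_censored"] = True
    return out
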