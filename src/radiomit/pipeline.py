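"""Scenario orchestration: extract -> harmonize -> phenotype -> evaluate.

The eight mitigation scenarios differ in three switches: the physical
neighbor offset used at extraction (3 or 5 mm), whether images are resampled
to the dataset-minimum voxel spacing before extraction, and which batch
variable set is harmonized (none / voxel-spacing / acquisition / both).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from radiomit import synthetic
from radiomit.features import (
    ExtractionParams,
    compute_min_spacing,
    extract_table,
    resample_image,
    save_nifti_pair,
)
from radiomit.harmonization import HarmonizationResult, nested_combat
from radiomit.phenotyping import PhenotypeResult, identify_phenotypes
from radiomit.prognosis import PrognosticReport, build_report, group_by_batch, nmi
from radiomit.types import CohortTable, FeatureTable

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "RunConfig",
    "ScenarioOutput",
    "run_scenario",
    "run_all",
    "make_fixtures",
    "FIXTURE_PRESETS",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One heterogeneity-mitigation scenario."""

    scenario_id: str
    offset_mm: float | None  # None = not applicable (default extraction offset)
    resample: bool
    batch_set: str  # none | voxel-spacing | acquisition | both

    def __post_init__(self) -> None:
        if self.batch_set not in {"none", "voxel-spacing", "acquisition", "both"}:
            raise ValueError(f"unknown batch set {self.batch_set!r}")


SCENARIOS: dict[str, ScenarioSpec] = {
    "original": ScenarioSpec("original", None, False, "none"),
    "1A": ScenarioSpec("1A", 3.0, False, "voxel-spacing"),
    "1B": ScenarioSpec("1B", 5.0, False, "voxel-spacing"),
    "2A": ScenarioSpec("2A", 3.0, False, "acquisition"),
    "2B": ScenarioSpec("2B", 5.0, False, "acquisition"),
    "3": ScenarioSpec("3", None, True, "acquisition"),
    "4A": ScenarioSpec("4A", 3.0, False, "both"),
    "4B": ScenarioSpec("4B", 5.0, False, "both"),
}


@dataclass
class RunConfig:
    """Validated run configuration; fully serialized for provenance."""

    output_dir: str = "output"
    features_csv: str | None = None
    cohort_csv: str | None = None
    images_manifest: str | None = None
    scenarios: list[str] = field(default_factory=lambda: list(SCENARIOS))
    alpha: float = 0.05
    n_bins: int = 32
    seed: int = 0
    k_min: int = 2
    k_max: int = 5
    n_subsamples: int = 60
    subsample_fraction: float = 0.8
    n_sim: int = 200
    with_cv: bool = False
    cv_folds: int = 5
    cv_iterations: int = 200
    voxel_spacing_vars: list[str] = field(default_factory=list)
    acquisition_vars: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    time_col: str = "time"
    event_col: str = "event"
    groupings: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = [s for s in self.scenarios if s not in SCENARIOS]
        if unknown:
            raise ValueError(f"unknown scenario ids: {unknown}")
        if self.features_csv is None and self.images_manifest is None:
            raise ValueError("either features_csv or images_manifest is required")
        if self.cohort_csv is None:
            raise ValueError("cohort_csv is required")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def batch_vars_for(self, batch_set: str) -> list[str]:
        return {
            "none": [],
            "voxel-spacing": list(self.voxel_spacing_vars),
            "acquisition": list(self.acquisition_vars),
            "both": list(self.voxel_spacing_vars) + list(self.acquisition_vars),
        }[batch_set]


@dataclass
class ScenarioOutput:
    scenario: ScenarioSpec
    features: FeatureTable
    harmonization: HarmonizationResult | None
    phenotype: PhenotypeResult
    stage_log: list[str]


def _extract_for_scenario(
    scenario: ScenarioSpec,
    images,
    patient_ids,
    config: RunConfig,
    stage_log: list[str],
    cache: dict | None = None,
) -> FeatureTable:
    key = (scenario.resample, scenario.offset_mm)
    if cache is not None and key in cache:
        stage_log.append(f"extract:cached{key}")
        return cache[key]
    if scenario.resample:
        target = compute_min_spacing(images)
        stage_log.append(f"resample:{tuple(round(t, 4) for t in target)}")
        images = [resample_image(img, target) for img in images]
    params = ExtractionParams(
        offset_mm=scenario.offset_mm or 3.0, n_bins=config.n_bins
    )
    stage_log.append(f"extract:offset={params.offset_mm}")
    table = extract_table(images, patient_ids, params)
    if cache is not None:
        cache[key] = table
    return table


def run_scenario(
    config: RunConfig,
    scenario: ScenarioSpec,
    features: FeatureTable | None,
    cohort: CohortTable,
    images=None,
    extraction_cache: dict | None = None,
    out_dir: Path | None = None,
) -> ScenarioOutput:
    """Run one scenario end to end and write its artifacts."""
    stage_log: list[str] = [f"scenario:{scenario.scenario_id}"]
    if images is not None:
        table = _extract_for_scenario(
            scenario, images, cohort.patients, config, stage_log, extraction_cache
        )
    else:
        if features is None:
            raise ValueError("no features and no images provided")
        table = features
        stage_log.append("extract:precomputed")

    harmonization = None
    batch_vars = config.batch_vars_for(scenario.batch_set)
    if batch_vars:
        stage_log.append(f"harmonize:{'+'.join(batch_vars)}")
        covs = (
            cohort.data[cohort.covariates] if cohort.covariates else None
        )
        harmonization = nested_combat(
            table, cohort.data[batch_vars], covs, alpha=config.alpha
        )
        table = harmonization.harmonized

    stage_log.append("phenotype")
    phenotype = identify_phenotypes(
        table,
        k_range=range(config.k_min, config.k_max + 1),
        n_subsamples=config.n_subsamples,
        subsample_fraction=config.subsample_fraction,
        n_sim=config.n_sim,
        alpha=config.alpha,
        seed=config.seed,
    )

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "features.csv")
        pd.DataFrame(
            {"patient_id": table.patients, "phenotype": phenotype.labels}
        ).to_csv(out_dir / "phenotypes.csv", index=False)
        pd.DataFrame(
            {
                "k": phenotype.consensus.k_values,
                "cdf_area": [
                    phenotype.consensus.cdf_areas[k] for k in phenotype.consensus.k_values
                ],
            }
        ).to_csv(out_dir / "consensus.csv", index=False)
        if harmonization is not None:
            pd.DataFrame(
                [
                    {"order": "->".join(order), "n_significant": count}
                    for order, count in harmonization.permutation_counts.items()
                ]
            ).to_csv(out_dir / "harmonization_orders.csv", index=False)
            pd.Series(harmonization.discarded, name="feature").to_csv(
                out_dir / "discarded_features.csv", index=False
            )
        with open(out_dir / "stage_log.txt", "w") as fh:
            fh.write("\n".join(stage_log) + "\n")
    return ScenarioOutput(scenario, table, harmonization, phenotype, stage_log)


def _load_inputs(config: RunConfig):
    features = (
        FeatureTable.from_csv(config.features_csv) if config.features_csv else None
    )
    cohort_df = pd.read_csv(config.cohort_csv, index_col="patient_id")
    all_batch = sorted(set(config.voxel_spacing_vars) | set(config.acquisition_vars))
    cohort = CohortTable(
        cohort_df,
        batch_variables=[v for v in all_batch if v in cohort_df.columns],
        covariates=config.covariates,
        time_col=config.time_col if config.time_col in cohort_df.columns else None,
        event_col=config.event_col if config.event_col in cohort_df.columns else None,
    )
    images = None
    if config.images_manifest:
        from radiomit.features import load_nifti_pair

        manifest = pd.read_csv(config.images_manifest)
        root = Path(config.images_manifest).parent
        images = [
            load_nifti_pair(root / row.image, root / row.mask)
            for row in manifest.itertuples()
        ]
        ids = list(manifest["patient_id"])
        cohort_df = cohort_df.loc[ids]
        cohort = CohortTable(
            cohort_df,
            batch_variables=cohort.batch_variables,
            covariates=cohort.covariates,
            time_col=cohort.time_col,
            event_col=cohort.event_col,
        )
    return features, cohort, images


def run_all(config: RunConfig) -> tuple[dict[str, ScenarioOutput], PrognosticReport, pd.DataFrame]:
    """Run every configured scenario; consolidate c-score and NMI tables.

    Writes per-scenario artifacts plus consolidated ``c_scores.csv``,
    ``nmi_vs_scenario3.csv`` and a run manifest under ``config.output_dir``.
    """
    features, cohort, images = _load_inputs(config)
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_root / "config.yaml")

    cache: dict = {}
    outputs: dict[str, ScenarioOutput] = {}
    for sid in config.scenarios:
        try:
            outputs[sid] = run_scenario(
                config,
                SCENARIOS[sid],
                features,
                cohort,
                images=images,
                extraction_cache=cache,
                out_dir=out_root / f"scenario-{sid}",
            )
        except ValueError as exc:
            warnings.warn(f"scenario {sid} failed: {exc}", stacklevel=2)

    groupings = []
    for spec in config.groupings:
        groupings.append(
            group_by_batch(
                cohort,
                spec["variable"],
                threshold=spec.get("threshold"),
                level_set=set(spec["levels"]) if "levels" in spec else None,
            )
        )

    report = build_report(
        {sid: out.features for sid, out in outputs.items()},
        cohort,
        groupings,
        seed=config.seed,
        with_cv=config.with_cv,
        cv_folds=config.cv_folds,
        cv_iterations=config.cv_iterations,
    )
    report.c_scores.to_csv(out_root / "c_scores.csv")

    nmi_rows = []
    if "3" in outputs:
        for (group, sid), labels in report.labels.items():
            ref = report.labels.get((group, "3"))
            if ref is None or sid == "3":
                continue
            nmi_rows.append(
                {"group": group, "scenario": sid, "nmi_vs_3": nmi(labels, ref)}
            )
    nmi_df = pd.DataFrame(nmi_rows)
    nmi_df.to_csv(out_root / "nmi_vs_scenario3.csv", index=False)

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {
            "radiomit": __import__("radiomit").__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "scenarios_completed": sorted(outputs),
    }
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outputs, report, nmi_df


FIXTURE_PRESETS = ("feature-only-small", "imaging-small", "confounded")


def _confounded_batch_design(gamma_kernel: float = 3.0) -> synthetic.BatchDesign:
    return synthetic.BatchDesign(
        variables=[
            synthetic.BatchVariable("spacing_group", ["lo", "hi"], [0.5, 0.5]),
            synthetic.BatchVariable(
                "kernel",
                ["soft", "sharp"],
                [0.75, 0.25],
                conditional_on="spacing_group",
                probs_by_level={"lo": [0.5, 0.5], "hi": [1.0, 0.0]},
            ),
        ],
        gamma={"kernel": {"sharp": gamma_kernel}},
        delta={},
    )


def simulate_preset(preset: str, seed: int = 0):
    """Build one of the named demo cohorts in memory.

    Returns ``(features, cohort, images)``; ``images`` is None for the
    feature-only presets and ``features`` is None for the imaging preset.
    """
    if preset == "feature-only-small":
        batch = synthetic.BatchDesign(
            variables=[
                synthetic.BatchVariable("spacing_group", ["lo", "hi"], [0.5, 0.5]),
                synthetic.BatchVariable("kernel", ["soft", "sharp"], [0.6, 0.4]),
            ],
            gamma={"spacing_group": {"hi": 0.8}, "kernel": {"sharp": 1.0}},
            delta={"kernel": {"sharp": 1.5}},
        )
        features, cohort = synthetic.simulate_feature_table(
            150, 60, batch, synthetic.PhenotypeDesign(effect_size=1.5, affected_fraction=0.3),
            covariate_effects=0.3, seed=seed,
        )
        cohort = synthetic.simulate_survival(
            cohort,
            synthetic.SurvivalDesign(
                baseline_rate=0.05,
                log_hazard_ratios={"phenotype": 1.0, "covar": 0.5},
                censoring_rate=0.02,
            ),
            seed=seed + 1,
        )
        return features, cohort, None
    if preset == "confounded":
        features, cohort = synthetic.simulate_feature_table(
            200, 60, _confounded_batch_design(),
            synthetic.PhenotypeDesign(effect_size=1.5, affected_fraction=0.3),
            covariate_effects=0.3, seed=seed,
        )
        cohort = synthetic.simulate_survival(
            cohort,
            synthetic.SurvivalDesign(
                baseline_rate=0.05,
                log_hazard_ratios={"phenotype": 2.0, "covar": 0.5},
                censoring_rate=0.01,
            ),
            seed=seed + 1,
        )
        return features, cohort, None
    if preset == "imaging-small":
        images, cohort = synthetic.simulate_images(
            60,
            base_shape=(40, 40, 40),
            spacing_by_batch={"fine": (1.0, 1.0, 1.2), "coarse": (1.4, 1.4, 2.4)},
            kernel_sigma_by_batch={"soft": 1.2, "sharp": 0.0},
            contrast_shift_by_batch={"ce": 80.0, "nc": 0.0},
            phenotype=synthetic.PhenotypeDesign(),
            seed=seed,
        )
        cohort = synthetic.simulate_survival(
            cohort,
            synthetic.SurvivalDesign(
                baseline_rate=0.05,
                log_hazard_ratios={"phenotype": 1.0, "covar": 0.5},
                censoring_rate=0.02,
            ),
            seed=seed + 1,
        )
        return None, cohort, images
    raise ValueError(f"unknown preset {preset!r}; choose one of {FIXTURE_PRESETS}")


def make_fixtures(preset: str, seed: int, out_dir) -> Path:
    """Write a self-describing demo cohort to disk; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    features, cohort, images = simulate_preset(preset, seed)
    cohort.to_csv(out / "cohort.csv")
    if features is not None:
        features.to_csv(out / "features.csv")
    if images is not None:
        rows = []
        for pid, img in zip(cohort.patients, images):
            image_path = f"images/{pid}_image.nii.gz"
            mask_path = f"images/{pid}_mask.nii.gz"
            save_nifti_pair(img, out / image_path, out / mask_path)
            rows.append({"patient_id": pid, "image": image_path, "mask": mask_path})
        pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    with open(out / "README.txt", "w") as fh:
        fh.write(
            f"preset: {preset}\nseed: {seed}\n"
            "files: cohort.csv (+ features.csv or manifest.csv + images/)\n"
        )
    return out
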