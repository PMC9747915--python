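# radiomit

Mitigation of image-parameter heterogeneity in radiomic biomarker pipelines:

- **feature extraction** from 3D ROI volumes with physical-unit neighbor
  offsets and anisotropic resampling to the dataset-minimum voxel spacing
  (intensity, histogram, volumetric, morphology, GLRLM, NGTDM and GLSZM
  families);
- **harmonization** of feature tables by parametric empirical-Bayes ComBat,
  extended to multiple batch variables by sequential (nested) application with
  k-sample Anderson–Darling order selection and discard of features that stay
  batch-affected;
- **phenotype discovery** by Ward/Euclidean hierarchical clustering with
  consensus-based k selection (PAC) and SigClust cluster-significance testing;
- **prognostic evaluation** per batch-variable group: Cox proportional-hazards
  models (phenotype + clinical covariates), apparent and cross-validated
  Harrell c-statistics, NMI between phenotype labelings, and chi-square
  covariate associations;
- a **synthetic-data module** that plants location/scale batch effects, latent
  phenotypes, image-level acquisition heterogeneity and proportional-hazards
  outcomes, so the whole pipeline is testable offline.

Eight mitigation scenarios are orchestrated end to end (`original`, `1A/1B`,
`2A/2B`, `3`, `4A/4B`), differing in extraction offset (3 vs 5 mm), resampling
to minimum voxel spacing, and which batch-variable set gets harmonized
(none / voxel spacing / acquisition / both).

## CLI

```bash
radiomit list-scenarios
radiomit fixtures  --preset feature-only-small --seed 0 --out demo/
radiomit harmonize --features demo/features.csv --cohort demo/cohort.csv \
                   --batch-vars spacing_group,kernel --covariates covar \
                   --out demo/harmonized.csv
radiomit phenotype --features demo/harmonized.csv --out demo/phenotypes.csv
radiomit run-all   --config config.yaml
```

`run-all` reads a YAML config (see `radiomit.pipeline.RunConfig` for the
schema: input CSVs or a NIfTI manifest, scenario list, batch-variable role
mapping, grouping thresholds, seeds) and writes per-scenario artifacts plus
consolidated c-score and NMI tables and a run manifest. Exit codes: 0 success,
2 config error, 3 stage failure.

## Library sketch

```python
from radiomit import synthetic
from radiomit.harmonization import nested_combat
from radiomit.phenotyping import identify_phenotypes

ft, cohort = synthetic.simulate_feature_table(
    200, 60,
    synthetic.BatchDesign(
        variables=[synthetic.BatchVariable("scanner", ["a", "b"], [0.5, 0.5])],
        gamma={"scanner": {"b": 1.0}}, delta={"scanner": {"b": 2.0}},
    ),
    synthetic.PhenotypeDesign(effect_size=1.5, affected_fraction=0.3),
    seed=0,
)
result = nested_combat(ft, cohort.data[["scanner"]], cohort.data[["covar"]])
phenotypes = identify_phenotypes(result.harmonized, seed=0)
```

## Conventions

- Voxel indices are 0-based; physical position = index × spacing (origin at
  the first voxel centre). Discretization is fixed-bin-number (default 32)
  over the ROI min–max range.
- GLRLM uses the 13 unique 3D directions with matrix averaging; GLSZM uses
  26-connectivity; the NGTDM neighborhood honors the mm offset per axis.
- Numeric batch-variable groupings split "< t" vs "≥ t" with boundary values
  in the "≥" group.
- All randomness flows through explicit integer seeds; reruns reproduce every
  CSV byte for byte.
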