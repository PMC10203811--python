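# restmem

Analysis pipeline linking resting-state BOLD amplitude fluctuations
(PerAF / mPerAF) to memory-encoding-related activity (the parametric
subsequent-memory effect, SME) across age groups, including the
voxel-wise multi-modal group GLM with imaging covariates, permutation
max-T family-wise error control, recognition-memory ROC/AUC scoring and
Bayesian Pearson correlations. A synthetic-data module generates
cohorts, rating tables and 4D rest/task images with known ground truth,
so every stage is testable without external MRI data.

## Modules

| module | contents |
| --- | --- |
| `restmem.amplitude` | `BoldSeries`, detrend + rectangular FFT band-pass (0.01–0.08 Hz), PerAF (`mean |y−μ|/μ·100`), global-mean normalization to mPerAF |
| `restmem.behavior` | arcsine parametric modulator `PM = arcsin((x−3)/2)·2/π`, confidence-rating ROC/AUC (≡ tie-corrected Mann–Whitney) |
| `restmem.firstlevel` | canonical double-gamma HRF, microtime design builder (novelty, novelty×PM, master, motion, constant), DCT high-pass + OLS fit, SME beta maps |
| `restmem.groupglm` | group design assembly (cells, group-wise centered scalar covariates, voxel-wise imaging covariates expanded per cell), per-voxel OLS, t-contrasts, Freedman–Lane permutation max-T FWE, cluster tables, overlap maps |
| `restmem.roistats` | sphere / labeled ROIs, ROI means, Bayesian Pearson correlation (stretched-beta prior, exact-density quadrature), ANCOVA + Levene, t / χ² / Mann–Whitney z |
| `restmem.cohort` | synthetic cohorts calibrated to the study demographics, signal-detection rating generator with AUC-calibrated separation, band-limited rest runs, task runs with injected SME effects, GMV covariate maps, geometric DMN ROI stand-ins |

## CLI

```sh
restmem simulate --config cohort.yaml --out study/ --seed 1 --images
restmem peraf --in rest.nii.gz --mask mask.nii.gz --band 0.01 0.08 --out mperaf.nii.gz
restmem score-memory --ratings ratings.tsv --out scores.json
restmem first-level --bold task.nii.gz --events events.tsv --motion mc.txt --out sme.nii.gz
restmem group --model model.yaml --cohort cohort.csv --maps maps.json --out group/
restmem roi-stats --rois rois.nii.gz --labels rois.json --maps maps.json --cohort cohort.csv --out table.csv
```

`maps.json` is `{modality: {subject_id: nifti_path}}`. A group model YAML
either names a canned model (`model: model1|model2|model3`, the three
hypothesis models with their published regressor layout) or lists
covariates explicitly, plus `contrasts` (name → column weights) and
`fwe` settings (`method`, `alpha`, `k`, `n_perm`, `strata`).

## Notes

- Family-wise error control uses permutation of the maximum statistic
  (Freedman–Lane under the reduced model, optionally stratified by
  scanner) rather than random-field theory; thresholds therefore differ
  numerically from parametric SPM output.
- The mPerAF normalization mask defaults to the brain mask minus
  QC-flagged (zero-mean / zero-variance) voxels; the mean of mPerAF over
  that mask is 1 by construction.
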