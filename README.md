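# restpipe

Multilevel resting-state fMRI analysis pipeline for two-group (patient vs
control) studies, driven by a synthetic 4D BOLD cohort generator so every
stage is testable without patient data.

The pipeline covers:

* **`synthetic_cohort`** — reproducible two-group BOLD cohorts on a
  desk-scale grid (default 24×24×16 voxels, 170 volumes at TR = 2 s) with
  injectable ground-truth group effects (low-frequency amplitude, local
  synchrony, hub connectivity, interhemispheric coupling, seed coupling),
  motion traces, WM/CSF-like nuisance components and a gray-matter
  probability map.
* **`preprocess`** — volume discard, 24-parameter motion + WM/CSF nuisance
  regression, 0.01–0.08 Hz band-pass, framewise displacement, motion
  exclusion screening (2 mm / 2°), gray-matter mask binarization
  (cutoff 0.2), Gaussian smoothing (FWHM 6 mm).
* **`local_metrics`** — voxelwise fALFF, ReHo (Kendall concordance with 26
  neighbors), weighted degree centrality (r > 0.25), VMHC and functional
  connectivity strength (r₀ = 0.2), with per-metric smoothing order and
  Fisher-z / z-score standardization.
* **`network_fc`** — seed-based Fisher-z connectivity maps for the 12
  built-in network seeds (6 mm spheres, MNI mm; see
  `src/restpipe/data/seeds.csv`).
* **`group_stats`** — voxelwise covariate-adjusted (age, sex, mean FD)
  two-sample t maps, residual smoothness estimation, Gaussian random field
  cluster-extent correction (voxel p < 0.001, cluster p < 0.01), cluster
  ROI feature extraction, and demographics tests.
* **`classifier`** — RBF-SVM per feature family (single metric, combined
  local, combined network): stratified 80:20 split, min–max rescaling
  fitted on training rows, nested stratified 5-fold grid search over
  C ∈ {1e-4…1e4} × gamma ∈ {1…1e-4} with balanced class weights, then
  repeated stratified 5-fold CV and hold-out evaluation (AUC, balanced
  accuracy, sensitivity, specificity, PPV, NPV, as percentages).
* **`explain`** — exact Shapley-value feature attribution of the decision
  scores (coalition enumeration for ≤12 features, seeded permutation
  sampling above) and top-k feature ranking.

## CLI

```bash
restpipe simulate --n-patients 10 --n-controls 10 \
    --effect falff_amplitude:0,0,0:9:5.0 --seed 1 --out-dir cohort/
restpipe preprocess --bold cohort/sub-000_bold.nii.gz \
    --motion cohort/sub-000_motion.txt --gm-prob cohort/gm_prob.nii.gz \
    --n-discard 10 --out pre/sub-000.nii.gz
restpipe metrics --bold pre/sub-000.nii.gz --gm-prob cohort/gm_prob.nii.gz \
    --which falff,reho,dc,vmhc,fcs --out-dir maps/
restpipe groupstats --maps-csv maps/listing.csv --gm-prob cohort/gm_prob.nii.gz \
    --voxel-p 0.001 --cluster-p 0.01 --out-dir stats/
restpipe classify --features stats/features.csv --family combined_local \
    --repeats 100 --seed 17 --out report.json
restpipe explain --features stats/features.csv --family combined_local \
    --top-k 20 --out-csv shap.csv
```

Every command also accepts `--config <yaml>` with option defaults.

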