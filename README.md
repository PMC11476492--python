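# perisk

A preeclampsia (PE) risk-prediction pipeline for bi-platform placental growth
factor (PlGF) data, built to be fully testable on synthetic cohorts:

* **synthetic cohorts** (`perisk.cohort`) — labelled case/control tables with
  class-dependent feature shifts (lower PlGF, higher blood pressure / BMI in
  cases), two strongly dependent feature pairs (pre-pregnancy vs. current
  weight as a function of gestational age; diastolic vs. systolic pressure),
  a five-level ethnicity factor, two measurement platforms linked by a known
  monotone transfer function, configurable missing-completely-at-random gaps,
  and small paired calibration sets;
* **feature encoding** (`perisk.encoding`) — the 14 collected variables are
  expanded into a fixed 22-column design matrix (one-hot ethnicity, BMI
  variables and their increase rate, gestational day, mean arterial pressure)
  with min–max normalization that always leaves PlGF on its raw scale;
* **imputation** (`perisk.imputation`) — class-conditional medians for
  training rows, overall medians for test rows, and relation-based imputation
  for the two dependent pairs via small 1-input / 2-hidden / 1-output sigmoid
  regressors (the weight pair stratified into five gestational-age
  intervals); test-time pair imputation uses class-free pooled regressors;
* **calibration** (`perisk.calibration`) — directional regressor pools
  trained under repeated 3-fold CV (default 100 × 3 = 300 candidates per
  direction), the median-rank model selected per direction, and the
  direction with the smaller selected MSE deployed; reference-platform
  values pass through unchanged;
* **prediction** (`perisk.prediction`) — random forest (primary) plus MLP,
  SVM, gradient-boosting and AdaBoost comparators, continuous risk scores,
  output thresholding, F1-optimal threshold search over a grid, and
  impurity-based feature-importance ranking;
* **evaluation** (`perisk.evaluation`) — confusion-derived metric bundles
  (error rate, TPR/FPR/TNR/FNR, F1, micro/macro-F1, AUC_ROC, AUC_PRC) and
  three repeated-CV protocols reporting median ± deviation across rounds:
  standard, early-enriched (folds partition the early-pregnancy subset only,
  all non-early data join every training fold), and
  augmented-with-real-only-testing (oversampling *before* the split, scored
  on all vs. real-only held-out records — the setup that exposes virtually
  high performance);
* **augmentation** (`perisk.augmentation`) — native interpolation-based
  minority oversampling (plain and k-means cluster-aware variants) at a
  configurable post-augmentation minority:majority ratio (default 1.2), with
  origin flags on every synthetic row and a pluggable backend registry;
* **experiments / CLI** (`perisk.experiments`, `perisk.cli`) — end-to-end
  seeded experiment drivers (`model_comparison`, `bi_platform_fusion`,
  `threshold_search`, `early_prediction`, `augmentation_study`) emitting
  JSON + aligned-text reports.

## CLI

```sh
perisk simulate --out-dir data              # synthetic cohorts + calibration pairs
perisk encode data/simoa.csv enc.csv
perisk impute --train data/simoa.csv --out-train imp.csv --model-out imp.json
perisk calibrate --pairs data/calibration_pairs.csv --report cal.json
perisk train --data data/simoa.csv --model-out model.joblib
perisk predict --model model.joblib --data imp.csv --out pred.csv --threshold 0.21
perisk evaluate --data data/simoa.csv --out cv.json
perisk experiment bi_platform_fusion --out-dir results
perisk report results/bi_platform_fusion.json
```

All commands accept `--config <yaml>` (see `perisk.config.validate_config`
for the schema; an empty file means "all defaults": study-shaped cohort
sizes, seed 0, 10 CV rounds) and `--seed` to override the master seed.
Default experiment scale is 10 rounds; the full 100 × 10-fold protocol is a
config change (`rounds: 100`).

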