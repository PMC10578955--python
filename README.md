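# qustex

Quantitative-ultrasound (QUS) radiomics in Python: from raw RF echo frames
through calibrated power spectra and seven-parameter parametric maps, to
gray-level texture features, higher-order *texture-of-texture* (TOT)
features, and a cross-validated SVM / k-NN classification harness.  The
package ships a first-class synthetic-data module so the entire pipeline is
testable end to end with known ground truth and no external data.

## Pipeline at a glance

1. **synthdata** — speckle RF frames from random point scatterers
   (controllable effective scatterer diameter, density, amplitude variance
   and attenuation), a calibration phantom with an analytic backscatter
   curve, and labelled multi-patient cohorts of parametric maps drawn from
   class-conditional Gaussian random fields.
2. **spectral** — Hamming-tapered, line-averaged window spectra; reference
   phantom normalization with point attenuation compensation
   (`+4·α·f·d` dB); best-fit line parameters MBF / SS / SI; backscatter
   model fits for ASD / AAC under a Gaussian form factor and a fluid-sphere
   (partial-wave) form factor.
3. **maps** — seven-parameter sliding-window maps (2×2 mm blocks, 94.1 %
   overlap; steps of 1 line laterally / 6 samples axially at the default
   40 MHz, 256-line geometry), ROI statistics and one-tailed group
   comparison.
4. **texture** — min–max discretization (16 levels), GLCM / GLRLM / GLSZM /
   GLDM matrices and their 22 + 16 + 16 + 14 = 68-feature catalog per map
   (476 per patient over 7 maps), 17 first-order features, and per-patient
   frame-averaged dataset assembly.
5. **tot** — texture-feature parametric maps built from 3×3 sliding windows
   of a QUS map, per-map TOT feature sets (68 texture + 17 first-order),
   and the enhanced 5-base + TOT dataset.
6. **mlpipe** — SMOTE (in-package), z-scoring, sequential forward selection
   by inner 5-fold F1, leave-one-out evaluation with pooled ROC/AUC, and
   the full two-stage protocol producing model-size report tables.

All preprocessing is nested inside training folds; a deliberately unsafe
global-SMOTE mode exists behind `unsafe_smote_global` for comparison.

## CLI

Two entry points are installed:

```sh
# data generation
synth rf      --seed 1 --config cfg.yaml --out frame.h5
synth phantom --seed 1 --config cfg.yaml --out phantom.h5
synth cohort  --seed 1 --config cfg.yaml --out cohort_dir/

# analysis
qus spectra  --input frame.h5 --phantom phantom.h5 --band 3:8 --out spectrum.csv
qus maps     --input frame.h5 --phantom phantom.h5 --out maps.h5
qus features --maps cohort_dir/ --out features.csv --ng 16
qus tot      --maps cohort_dir/ --base5 svm_top5 --out tot.csv
qus ml       --features features.csv --config cfg.yaml --out report_dir/
qus run-all  --seed 1 --config cfg.yaml --out run_dir/
```

`qus run-all` executes synth → features → TOT → both classifiers and emits
per-classifier, per-stage report tables (model sizes 1..7 with sensitivity,
specificity, accuracy, precision and AUC) plus a JSON summary.  YAML config
keys: `acquisition`, `scatterers`, `cohort`, `window`, `band`, `pipeline`.
Packaged base-5 presets for TOT generation: `svm_top5`, `knn_top5`.

## Layout

```
src/qustex/
  core.py        shared domain types (acquisition spec, RF frame, maps)
  synthdata/     RF + phantom simulation, GRF cohorts
  spectral.py    spectra, line fits, form factors, BSC fitting
  maps.py        sliding-window maps, ROI stats, group comparison
  texture/       discretization, matrices, features, dataset assembly
  tot.py         texture-of-texture maps and datasets
  mlpipe.py      SMOTE, scaling, SFS, LOOCV, reports
  io.py          HDF5 containers
  cli.py         `qus` and `synth` entry points
  presets/       base-5 feature presets
```
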