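# soilhsi

Analysis pipeline for near-infrared hyperspectral images of soil samples:
classification of soil types from fused spectral + image-texture features,
and calibration of soil total nitrogen (TN, % dry mass) with local
(per-soil-type) versus general (pooled) regression models.  A synthetic
cohort generator with the same statistical structure ships with the
package, so the entire pipeline runs and is tested without any external
data.

The package is aimed at chemometrics / imaging-spectroscopy practitioners
who want a reproducible, leakage-free reference implementation of this
spectral-texture fusion workflow.

## The method

Each soil sample is imaged as a reflectance cube (rows × cols × bands,
975–1645 nm, 200 bands).  Raw frames are corrected against white and dark
references,

&nbsp;&nbsp;&nbsp;&nbsp; *I* = (*I*₀ − *D*) / (*W* − *D*) × 100 %,

and a region of interest (50 × 50 px) is averaged into one mean spectrum
per sample.  The pipeline then runs two experiments:

**Soil-type classification.**  Spectra are preprocessed with SNV
(per-spectrum standardisation) followed by z-score scaling fitted on the
calibration split.  The **successive projections algorithm (SPA)** selects
a small set of *effective wavelengths* (EWs) with minimal collinearity: it
grows candidate chains by repeatedly appending the band whose projection
onto the orthogonal complement of the selected bands has maximal norm,
scores every chain prefix by the leave-one-out RMSECV of a multiple linear
regression, and sizes the subset with an *F*-test (α = 0.25) against the
curve minimum.  **GLCM texture features** (energy, contrast, homogeneity,
entropy; distance 1; directions 0°/45°/90°/135°, direction-averaged) are
extracted from the gray-scale ROI image at each EW — 4 × *k* features for
*k* EWs.  RBF-kernel SVMs with grid-searched (c, g) are trained on four
input sets: full spectrum, EWs, texture, and fused EW + texture.

**TN prediction.**  PLSR models (latent dimension by leave-one-out
RMSECV) are calibrated per soil type (*local*) and on the pooled cohort
(*general*), on the full spectrum and on TN-selected EWs, and judged on a
held-out 2:1 prediction split by RMSEP, R² = 1 − SSres/SStot and
RPD = SD(reference)/RMSEP.

All model selection (SPA, z-score statistics, SVM grids, PLSR dimension)
sees calibration samples only.

## Worked example

```python
import soilhsi as sh

config = sh.ExperimentConfig(seed=1)      # default synthetic cohort: 84/57/42 samples
report = sh.run_experiment(config)
print(sh.report_render(report))
```

prints (the RNG is fully seeded, so this output is reproducible):

```
Soil-type classification (SVM, RBF kernel)
input set                   vars                (c, g)   cal acc  pred acc
full_spectrum                200     (8192, 3.052e-05)    100.0%     98.4%
effective_wavelengths          6      (2048, 0.007812)    100.0%     86.9%
texture                       24        (32, 0.007812)     91.0%     88.5%
fused                         30     (2048, 0.0001221)     95.9%     96.7%
effective wavelengths (nm): 975.0, 1039.0, 1133.2, 1257.8, 1328.5, 1507.0

Soil TN prediction (PLSR)
scope                   input set                  NV  LV    RMSEP     R2   RPD
paddy                   full_spectrum             200   5   0.0577   0.23   1.2
paddy                   effective_wavelengths       6   6   0.0549   0.30   1.2
red                     full_spectrum             200   4   0.0382   0.59   1.6
red                     effective_wavelengths       3   3   0.0338   0.68   1.8
seashore_saline         full_spectrum             200  10   0.0326   0.37   1.3
seashore_saline         effective_wavelengths      11   9   0.0287   0.51   1.5
general                 full_spectrum             200   5   0.0431   0.63   1.7
general                 effective_wavelengths       5   5   0.0427   0.63   1.7
summary[full_spectrum]: mean local RMSEP 0.0428 vs general RMSEP 0.0431
summary[effective_wavelengths]: mean local RMSEP 0.0391 vs general RMSEP 0.0427
```

Reading the tables: on this seed the fused spectral+texture classifier
reaches 96.7% held-out accuracy versus 86.9% for effective wavelengths
alone — the texture block carries class information the spectra lack.  For
TN, six EWs match the 200-band model (general scope: R² 0.63 both), and
the local calibrations edge out the pooled general model in mean RMSEP.
Per-soil-type R² values are lower than the pooled ones because each class
spans a narrower TN range.

A thin CLI wraps the same calls:

```sh
soilhsi simulate --out cohort/ --seed 1          # ENVI cubes + manifest.csv
soilhsi run --out results/ --seed 1              # both experiments -> report.json/.txt
```

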