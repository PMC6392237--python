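# coralhsi

Classification of cold-water coral (*Lophelia pertusa*) health/exposure
status from underwater hyperspectral imagery, as a tested, reusable Python
package. It covers the full analysis chain:

1. **synthetic** — synthetic tank scenes (forward optical model with water
   attenuation, a Spectralon reference panel, an inclined PVC plate, coral
   sample blobs of two color morphs) plus simulated exposure-chemistry and
   polyp-mortality tables. No raw images are publicly deposited for this
   kind of experiment, so the generator is a first-class, tested module that
   gives every downstream stage a ground-truth oracle.
2. **radiometry** — reflectance calibration: per-column conversion factors
   from the Spectralon panel, PVC reflectance transfer, height-resolved
   conversion factors from the inclined plate, and per-pixel conversion of
   recorded intensity to reflectance at the sample height.
3. **spectral_db** — extraction of labeled pixel spectra into an `X` matrix
   (rows = pixels, columns = wavelengths), the 400–750 nm crop (619 columns
   on the default grid), and annotation with beaker mean concentration,
   polyp mortality (`Y_h`) and the exposure category (`Y_c`).
4. **exposure_chem** — summaries of measured toxicant concentrations
   (avg / std dev / min / max at beaker, group and stock level,
   percent-of-nominal, low-replicate flagging).
5. **dose_response** — binomial GLM with logit link on log-concentration
   (mortality → 0 as C → 0), closed-form LC5/LC25 inversion,
   case-resampling bootstrap CIs, and the exposure-category rule
   (low ≤ 1.25 < medium ≤ 2.30 < high, mg/L).
6. **classify** — per-morph pipelines: column standardization → PLS
   dimensionality reduction (default 10 latent variables, selectable by
   5-fold stratified CV) → ν-SVM (ν = 0.1, RBF), precision/recall/F1
   reporting with pixel-weighted harmonic totals, and per-sample majority
   voting with severity-biased tie-breaks.
7. **cli** — stage orchestration.

## CLI

```sh
coralhsi demo --out scratch/run --seed 1       # full synthetic end-to-end
coralhsi simulate --out scratch/run --seed 1   # or stage by stage:
coralhsi calibrate --run scratch/run
coralhsi extract --run scratch/run
coralhsi dose-response --polyps scratch/run/truth/samples.csv \
    --out scratch/run/dose_response.json
coralhsi fit --run scratch/run
coralhsi classify --run scratch/run
coralhsi report --run scratch/run
```

Scenes are written as ENVI header + band-sequential binary, calibrations as
HDF5, tables as CSV, scenario configuration as one YAML file. Exit codes:
0 ok, 1 user error, 2 internal error.

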