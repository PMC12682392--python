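# aptwi

Quantification and statistical analysis for predicting pathologic complete
response (pCR) to neoadjuvant chemotherapy in breast cancer from
pre-treatment amide proton transfer-weighted (APTw) MRI, diffusion-weighted
imaging, and early post-contrast enhancement — aimed at imaging scientists
who want the full chain from raw saturation-offset volumes to a fitted
prediction model, reproducible end to end on synthetic data.

## What it computes

**APTw contrast.** The Z-spectrum samples the water signal S(Δω) under
off-resonance saturation at Δω ∈ {±2.7, ±3.5, ±4.3} ppm, with an
unsaturated reference S₀. After voxel-wise B0 correction, the amide signal
is quantified as the magnetization transfer ratio asymmetry

    MTRasym(3.5 ppm) [%] = (S(−3.5) − S(+3.5)) / S₀ × 100 .

B0 maps come from multi-echo phase images: the off-resonance frequency is
the least-squares slope of unwrapped phase vs echo time over 2π, converted
to ppm with the scanner frequency (127.728 MHz at 3 T). Each branch of the
Z-spectrum is resampled at the shifted offsets by 3-point quadratic
(Lagrange) interpolation. Companion maps: mono-exponential ADC from
ln S vs b, and early net enhancement (post − pre).

**Histogram radiomics.** Whole-tumor 3-D ROIs (necrotic/cystic regions
excluded) yield first-order features per map: mean, SD, RMS, mean absolute
deviation, percentiles (1–99th), interquartile range, skewness, kurtosis.
Two readers' features are averaged; inter-reader agreement is ICC(2,1).

**Statistics.** Shapiro–Wilk-gated t / Mann–Whitney group comparisons;
chi-square (Yates when min expected < 5) or Fisher's exact test for
categoricals, Monte-Carlo exact test for sparse r×c tables; univariate and
forward-stepwise multivariate logistic regression (likelihood-ratio entry
at p < 0.05, removal at p > 0.10); ROC with DeLong standard errors and
Youden cutoffs; DeLong's paired test for comparing correlated AUCs.

**Synthetic data.** A Lorentzian-pool digital phantom with analytic
MTRasym ground truth, smooth polynomial B0 fields and reader-mask jitter;
and a patient-cohort generator with class-conditional categorical/feature
structure or a logistic-outcome mode with user-set true odds ratios.

## Worked example

```python
import numpy as np
from aptwi import phantom, cest, histogram

scene = phantom.default_scene(seed=1)
bundle = phantom.simulate_phantom_volumes(scene)
b0 = cest.estimate_b0_shift(bundle["phases"], bundle["echo_times_s"],
                            bundle["field_mhz"])
apt = cest.quantify_mtrasym_volume(bundle["offset_stack"], bundle["s0"],
                                   scene.offsets_ppm, b0=b0)
roi = histogram.extract_roi(apt, bundle["mask_tumor"],
                            exclusion_mask=bundle["mask_core"])
f = histogram.compute_features(roi)
print(f"solid-tumor voxels: {f.n_voxels}")
print(f"MTRasym mean {f.mean:.2f}%  p5 {f.p5:.2f}%  IQR {f.iqr:.3f} pp")
```

prints

```
solid-tumor voxels: 424
MTRasym mean 3.17%  p5 3.17%  IQR 0.001 pp
```

— the quantified tumor mean matches the phantom's analytic ground truth
(3.17%) despite the simulated B0 field of up to ±0.38 ppm, and the
near-zero IQR reflects the noise-free, homogeneous tumor: the correction
residual is the only spread.

The same stages run from the shell:

```
aptwi simulate phantom --seed 1 --out phantom/
aptwi quantify apt --config cfg.yaml --in phantom/ --out maps/
aptwi features --map maps/mtrasym_pct.nii.gz --mask phantom/mask_tumor.nii.gz --out features.csv
aptwi simulate cohort --seed 8 --n 150 --out cohort.csv
aptwi stats run --cohort cohort.csv --out results/
```

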