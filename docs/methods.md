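# Methods

## Quantification model

The saturated water signal is treated per voxel as a Z-spectrum Z(Δω) with
an unsaturated reference S₀ acquired far off-resonance; APTw contrast is
the asymmetry MTRasym(3.5 ppm) = (S(−3.5) − S(+3.5))/S₀ × 100%. Positive
values indicate net amide-proton transfer in excess of the (asymmetric)
background; negative values can occur and are preserved.

**B0 estimation.** The water frequency offset is estimated from ≥3 echo
phase images: phases are unwrapped along the echo axis (adding multiples of
2π to minimize successive jumps), the per-voxel least-squares slope of
phase vs echo time gives Δf = slope/2π in Hz, and shift_ppm = Δf/f₀ with
f₀ = 127.728 MHz at 3 T (42.576 MHz/T). Apparent shifts ≥ 2 ppm are kept
but flagged unreliable and excluded from map generation; such voxels come
out NaN rather than silently wrong.

**Z-spectrum correction.** The corrected signal at nominal offset Δω is
the measured spectrum evaluated at Δω + shift, interpolated separately on
the negative- and positive-offset branches by 3-point Lagrange (quadratic)
interpolation. With only three samples per branch the quadratic through all
of them is the highest-order interpolant available and is exact for branch
signals of polynomial degree ≤ 2. A target offset that leaves its sampled
branch (|shift| large relative to the 0.8 ppm edge margin) yields NaN for
that sample; shifts ≥ half the branch span (0.8 ppm for the nominal
schedule) are rejected outright. NaN propagates to the map and is dropped
at ROI extraction — invalid voxels are never zero-filled.

**ADC.** Mono-exponential: per-voxel least-squares slope of ln S vs b over
all b-values (two b-values reduce to ln(S_low/S_high)/(b_high−b_low)),
reported ×10⁻³ mm²/s. Non-positive signals make the voxel NaN. The b-value
schedule is configurable (default 0/500/1000 s/mm²) since acquisition
protocols vary.

**Net enhancement** is the voxel-wise early post-contrast minus
pre-contrast difference; no pharmacokinetic modelling is attempted.

All grids use 0-based voxel-index coordinates; masks and maps must be
congruent (no resampling in scope).

## Digital phantom

Saturation is modelled as a superposition of Lorentzian pools,
Z(Δω) = 1 − Σₖ Aₖ(wₖ/2)²/((wₖ/2)² + (Δω − δₖ − b0)²), rather than a full
exchange (Bloch-McConnell) simulation: the Lorentzian model has a closed
form at every offset, so MTRasym, its linearity in amide amplitude, and the
effect of any B0 shift have analytic ground truth usable as test oracles.
The cost is realism in line shapes and the absence of exchange-rate or
B1-dependence effects.

Default pools: a broad background line at 0 ppm (depth 0.88, FWHM 7.0 ppm,
representing direct water saturation merged with the semi-solid MT
background) and an amide line at +3.5 ppm (depth 0.035, FWHM 4.5 ppm),
giving tumor MTRasym ≈ 3.2%, in the range reported for breast lesions. The
widths are at the broad end of plausible: they are chosen so the spectrum
is smooth at the sparse 0.8 ppm offset spacing, making the correction
stage's accuracy contract achievable — 3-point quadratic resampling then
recovers MTRasym to < 0.1 percentage points for B0 shifts up to 0.5 ppm
(the residual of the default pools is ≤ 0.05 pp). Narrower lines at this
sampling density leave interpolation residuals of several tenths of a
point, which would be a property of the sampling schedule, not of the code.

The scene is a 24×24×6 grid (1.5×1.5×3 mm voxels) with an ellipsoidal
tumor, a necrotic core (high ADC, no amide, weak enhancement) and
background; the B0 field is a low-order in-plane polynomial (default up to
±0.38 ppm), smooth as scanner shim residuals are. Noise is additive
Gaussian on saturated signals only, S₀ noiseless, keeping the MTRasym noise
model analyzable; Rician noise, coil profiles, motion and anatomy are out
of scope, so passing round-trip tests demonstrate correctness of the
estimators, not robustness to real-scanner artifacts.

Reader-mask variants flip boundary voxels (inner and outer shells up to
`jitter_vox` layers, flip probability 0.3) rather than applying whole-shell
morphological erosion/dilation: voxel-wise flips reproduce the small,
spatially irregular disagreements of human readers (Dice ≈ 0.9 for unit
jitter on a 20-voxel object), whereas full-shell operations shift the
entire surface and understate agreement.

## Histogram features

Percentiles use linear interpolation with plotting position h = (n−1)q + 1
(the numpy default). "RMS" is √(Σx²/n) following the first-order radiomics
convention; the alternative reading (= SD) is exposed as the separate `sd`
feature so downstream selection can use either. Mean absolute deviation is
about the mean. Skewness and excess kurtosis are the bias-uncorrected
standardized sample moments; they are NaN below n = 3/4 and on
zero-variance samples. ICC is ICC(2,1) — two-way random effects, absolute
agreement, single measure — the stricter conventional choice for
interchangeable readers; a systematic offset between readers lowers it.

Physical ADC maps can legitimately produce only positive values, yet
published group summaries for low ADC percentiles are sometimes negative,
implying a standardization or offset in custom analysis code; this package
computes physical ADC and does not emulate such offsets. The cohort
generator, which works at the feature level, reproduces negative low
percentiles where a study reports them.

## Synthetic cohorts

Two modes, because group-comparison tables and outcome models describe
different factorizations of the joint distribution:

* **conditional mode** — label ~ Bernoulli(prevalence 43/108), then
  categoricals from class-conditional probabilities and features from
  class-conditional normals with an exchangeable correlation (default
  ρ = 0.8 within a feature family, e.g. the MTRasym percentiles, which are
  strongly dependent by construction). The shipped default spec encodes the
  class-conditional frequencies (ER, PR, HER2, Ki-67, menopause, grade,
  node, molecular subtype) and feature means/SDs of the 108-patient study;
  median(IQR) summaries are approximated as normal with sd = IQR/1.349.
* **voxel-derived mode** — each patient gets an explicit voxel sample
  (normal, with a random 0–20% colder subpopulation emulating unexcluded
  low-signal tissue) run through the histogram stage, so every percentile
  feature is internally consistent (monotone order, exact IQR identity).
* **logistic mode** — covariates drawn marginally, outcome ~
  Bernoulli(expit(β₀ + βᵀx)) with user-set true coefficients; used for
  parameter-recovery and stepwise-selection experiments.

The normal feature model ignores the skewness some features show in real
cohorts (a lognormal option is plausible future work); recovery results on
it validate the estimators, not distributional robustness.

## Statistical chain

* Normality gate: Shapiro–Wilk (Royston AS R94, 3 ≤ n ≤ 5000) at α = 0.05
  per group; both normal → t-test (Welch when a two-sided variance-ratio F
  test rejects equal variances at 0.05, else pooled), otherwise
  Mann–Whitney U with normal approximation and tie correction.
* 2×2 tables: Pearson chi-square, df 1; Yates continuity correction
  exactly when the minimum expected count is in [1, 5); below 1 the caller
  is directed to Fisher's exact test. This rule reproduces the published
  statistics of the reference cohort for every internally consistent row
  (Pearson for six factors, Yates for Ki-67 whose minimum expected count
  is 4.78). r×c tables with sparse cells use a fixed-margins Monte-Carlo
  exact test (Patefield sampling, add-one p estimate, ≥10⁴ replicates).
* Logistic regression: Newton-Raphson ML (tolerance 1e-8, ≤100
  iterations), Wald SEs from observed information, ORs with
  exp(β ± 1.96 SE) CIs. Separation is detected (statsmodels'
  perfect-prediction warning, or |β| > 15) and raised as an explicit
  error instead of returning runaway estimates. Both the Wald z and its
  square (the chi-square form some reports print) are carried on each term.
* Stepwise selection: forward by smallest likelihood-ratio p among
  excluded candidates, enter at p < 0.05; after each entry, included terms
  with LR p > 0.10 against their reduced model are dropped. Candidate
  order and ties resolve lexicographically, making selection
  deterministic; an exact duplicate of an included predictor adds no
  likelihood and is never admitted.
* ROC: AUC is the trapezoidal area, equal to the normalized Mann-Whitney
  U with ties counted ½; SE and CI by DeLong placement values; the cutoff
  is the smallest observed score attaining the maximum Youden index with
  the "score ≥ cutoff → positive" convention, orientation auto-flipped
  when the raw AUC < 0.5. DeLong's paired test compares correlated AUCs
  via the placement-value covariance.
* All p-values two-sided; no multiplicity adjustment (the report carries
  the number of tests run instead).

## Verification scale and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible.
Test problem sizes: conditional-frequency recovery at n = 10⁵ (±0.01),
coefficient recovery with generative ORs 0.16 / 7.25 / 1.35 at n = 2000
over 200 replicates (≥93% CI coverage), model-dominance at n = 300 over
100 replicates under strong effects (OR 0.1 / 10 / 2 per unit — values
chosen to represent a clearly separated regime), phantom round-trips on
the 24×24×6 default scene. The oracle-equivalence suite checks AUC against
brute-force pair counting on 1000 random sets, Fisher's exact p against
full enumeration, the chi-square statistic against the closed formula, and
the DeLong variance against a leave-one-out jackknife (within 10% at
n = 40).

## Known limitations

No DICOM ingestion, registration, motion or fat-suppression modelling; no
Bloch-McConnell exchange physics; no survival endpoints, calibration or
cross-validation of the prediction model. The phantom's homogeneous
regions make ROI histograms nearly degenerate (spread comes only from the
B0 residual), so distribution-shape features are exercised by the cohort
generator, not the phantom. Published cohort AUCs and cutoffs cannot be
reproduced without the original patient-level data; the package
substitutes the recovery/dominance/round-trip properties above.
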