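# Methods

This note documents the models, numerical choices and limitations behind
neutromet. It describes what the code computes; every empirical claim
here is reproduced by the test suite or by `scripts/acceptance.py`.

## 1. Spectral model of the synthetic generator

The generator emulates a titration experiment on extracted cell
metabolomes: cell counts of 100 k, 200 k, 400 k, 800 k, 1.6 M, 3.2 M and
5 M cells, acquired at 256, 512, 1024 and 2048 scans (NS), seven
replicates per condition. One spectrum is

I(δ) = Σ_m s_m · c · r_m(c) · Σ_k A_mk · L(δ; δ_mk + ε_m, γ_mk)
     + b(δ) + w(δ) + TSP(δ) + η(δ)

* **Line shape.** `L` is a unit-height Lorentzian — the standard
  solution-state NMR line. Peak FWHM values are 0.0018–0.0025 ppm
  (1.3–1.8 Hz at 700 MHz).
* **Signal scale.** `s_m` is signal per cell (arbitrary units,
  `1e-6 × relative abundance`); a unit-abundance peak at 400 k cells has
  height ≈ 0.4.
* **Recovery.** `r_m(c) = c⁴/(c⁴ + K_m⁴)` models concentration-dependent
  sample-prep loss: labile low-abundance metabolites survive extraction
  above a threshold cell count and are essentially absent below it. The
  default library grades `K_m` from 0 (robust: lactate, acetate,
  glutamate, creatine, taurine, glycine, formate) through mild loss
  (100–250 k: amino acids, myo-inositol, aromatics) to sharp thresholds
  between 200 k and 400 k cells (proline, mannose, acetone,
  acetoacetate, ATP; NAD at 500 k). `K_m = 0` recovers a signal exactly
  linear in cell count, which is the default for user-constructed
  metabolites and the case covered by the linearity tests. Without this
  term, TA normalisation cancels the cell count exactly and the
  titration conditions would be statistically indistinguishable in the
  mean — the compositional change with input amount is the phenomenon
  the pipeline is built to resolve.
* **Noise.** η is i.i.d. Gaussian per point with
  SD = `noise_sigma_ref · √(NS_ref/NS)`; the SD, not the variance,
  scales with 1/√NS, giving the √2 SNR gain per doubling of scans.
  `noise_sigma_ref = 0.05` at NS_ref = 256 places a unit-abundance peak
  at 100 k cells at SNR 2 — near/below the SNR-3 detection limit — and
  at SNR ≈ 5.7 at NS 2048, so the lowest cell count is recoverable only
  at high scan numbers.
* **Baseline.** A random degree-5 Bernstein polynomial with amplitude
  2.0 per spectrum, independent of cell count (baseline distortion is an
  instrument/water-suppression effect, not a sample property).
* **Water hump.** A Gaussian at 4.70 ppm (σ = 0.10 ppm), amplitude 5.0,
  confined to the 4.40–5.00 ppm exclusion window.
* **Chemical-shift jitter.** ε_m ~ N(0, 0.002 ppm) applied per
  metabolite — all of a metabolite's peaks move together, as pH/ionic
  strength shifts do. Bins are ±0.012 ppm wide, so jitter perturbs the
  captured area fraction by well under 1%.
* **TSP.** A constant-amplitude singlet at 0 ppm (FWHM 0.0012 ppm ≈
  0.84 Hz): an added internal standard does not scale with cell count.

Per-spectrum seeds derive deterministically from the cohort seed via a
`SeedSequence`, so identical configurations give bit-identical cohorts.

**What the generator does not emulate:** CPMG relaxation filtering and
J-coupling fine structure (peaks are single Lorentzians, not
multiplets), water-suppression artefact shapes beyond a smooth hump,
phase errors, ridge/smile baseline artefacts, and between-donor
biological variance. Passing tests therefore demonstrate correctness of
the pipeline's algorithms under a controlled spectral model, not
instrument-grade robustness.

## 2. Preprocessing

Order of operations: baseline correction → TSP referencing → line-width
QC → water exclusion. Baseline comes first because both the referencing
peak-prominence rule (apex > 3× median |intensity| in the ±0.2 ppm
window) and the half-height line-width measurement presuppose a locally
flat baseline.

* **Baseline.** A degree-5 (default) Bernstein polynomial is fitted by
  ordinary least squares to 16 (10–20 allowed) anchor points and
  subtracted. Auto anchors implement a rolling lower-quantile envelope:
  the axis is cut into `n_anchors` equal segments, annotated bins, the
  water window and the TSP region are excluded, and each segment
  contributes the point whose boxcar-smoothed (window 51) intensity is
  closest to the mean of the segment's 5th–25th percentile band. Fitting
  the smoothed value *at* the chosen point keeps polynomial baselines
  exactly nested (a cubic drift is removed to numerical precision);
  averaging a percentile band rather than taking a single low point
  keeps single-spectrum noise out of the fitted curve, which otherwise
  propagates a per-spectrum offset (~noise SD/3) into every bin
  integral. The boxcar's systematic offset `W²b″/24` is removed using
  the fitted polynomial's own curvature. Explicit anchor lists are
  supported for manual-adjustment workflows and use raw intensities.
* **Referencing.** The apex of the tallest peak in the search window is
  refined by parabolic interpolation, so re-referencing is the identity
  to well under one axis step.
* **Line-width QC.** FWHM by linear interpolation of the half-height
  crossings, converted as `Hz = ppm × spectrometer MHz`. The <1 Hz
  acceptance threshold is applied to the TSP singlet (the instrument
  criterion is defined on a separate standard sample, which a data-path
  library cannot see; TSP is the in-spectrum proxy). Failed spectra are
  excluded from statistics and listed in the run manifest.
* **Water exclusion.** Points in the closed 4.40–5.00 ppm interval are
  removed. Exclusion (rather than correction) is the default and is
  configurable.

## 3. Features

* **Integration.** Trapezoidal integral over [right, left] ppm with the
  intensity linearly interpolated at the exact boundaries, making
  adjacent sub-bins tile exactly (splitting a bin at any point conserves
  area to 1e-9). Negative integrals are floored at 0 with a logged
  warning — at 100 k cells baseline undershoot is routine and a hard
  error would make the detection-limit study impossible.
* **TA normalisation** divides each sample's row by its row sum
  (per-sample, hence leakage-free by construction).
* **Pareto scaling** centres each column and divides by √SD (sample SD,
  n−1); zero-variance columns are centred only. Pareto is the usual
  metabolomics compromise: it lifts low-intensity bins less aggressively
  than autoscaling, so large peaks are not drowned by noise-dominated
  variables.
* **CRS.** The correlation reliability score of a candidate bin is its
  mean Pearson correlation with the other candidate bins of the same
  metabolite, computed on the TA-normalised table across the whole
  cohort (scores are in [−1, 1]; a single candidate scores 1 by
  convention). The representative is the argmax; exact ties break by
  larger median intensity in the supplied table, then lexicographic
  bin id, and are flagged. Unannotated ("unknown") bins are removed;
  non-representative annotated candidates are recorded separately from
  the unknown removals. Correlations across the whole cohort (not
  within groups) are the default because reliability is a property of
  the measurement, not of a contrast.

## 4. Multivariate models

* **PCA** by SVD of the defensively re-centred matrix; deterministic
  sign convention (largest-magnitude loading element positive);
  explained-variance ratios are fractions of total variance.
* **PLS-DA** is NIPALS PLS2 against a column-centred dummy class matrix
  (two dummy columns even for two classes, for symmetry with
  multi-class). Per component: `w ∝ Xᵀu`, `t = Xw`, `q = Yᵀt/tᵀt`,
  `u = Yq` until `‖Δt‖ < 1e-10` (max 500 iterations, error on
  non-convergence), then deflation of X by `t pᵀ` and Y by `t qᵀ`.
  Weight columns are unit norm; score columns are orthogonal by the
  deflation property.
* **Prediction** projects test samples with the rotation `W(PᵀW)⁻¹` and
  assigns the class whose training-score mean is nearest in Mahalanobis
  distance under the pooled within-class score covariance with ridge
  `1e-6 · trace/K`. Pooled (not per-class) covariance because test folds
  here are tiny (n ≈ 7–15); the ridge guarantees invertibility. The
  same rule is used for all predictions and for BER, keeping the model
  coherent; a max-distance rule would be the alternative if exact parity
  with other toolchains were needed.
* **VIP.** `VIPⱼ = √(p · Σ_a SSYₐ w²ⱼₐ / Σ_a SSYₐ)` with
  `SSYₐ = ‖qₐ‖² tₐᵀtₐ`; computed from the NIPALS weights W (not rotated
  weights — implementations differ and this is the stated choice). The
  identity `Σ VIP² = p` holds exactly and is asserted for every fitted
  model in the suite.

## 5. Validation scheme

Ten replicates of a stratified random 70:30 split (per-class ceil
rounding for the train side, capped so every class keeps at least one
test sample). Within each training split, leave-one-out cross-validation
computes BER (mean of per-class error rates) for every candidate
component count; the chosen K is the argmin with ties to the smaller K —
a deterministic stand-in for manual component selection. Pareto
centering/scaling statistics are learned on the training portion of each
split (and of each LOOCV fold) only. Test metrics — accuracy, balanced
accuracy, sensitivity, specificity, precision, F1, BER — are aggregated
as mean ± SD across replicates; VIP scores and the count of variables
with VIP > 1 are recorded per replicate. Multi-class metrics are
macro-averaged, consistent with the balanced-error philosophy.

LOOCV requires ≥ 3 samples per class so that every fold retains the ≥ 2
per class the PLS-DA fit needs; the 70:30 scheme requires ≥ 4.

The univariate screen applies Student's *t* (two groups) or one-way
ANOVA with Tukey HSD post hoc pairs (more groups) per variable,
Benjamini–Hochberg step-up across variables (on the omnibus p for the
ANOVA case; Tukey adjusts within variable), with Shapiro–Wilk W and p
reported per variable and group but not used to gate the parametric
tests — reporting and testing are deliberately decoupled.

## 6. Detection limit

A bin is "detected" in a condition when its mean SNR across replicates
exceeds 3, with SNR = (boxcar-5 smoothed peak height in the bin) /
(noise SD). Noise SD is estimated from first differences in a
signal-free region (9.55–9.95 ppm): differencing annihilates smooth
baseline structure and `SD(diff)/√2` recovers the point noise SD. The
light smoothing keeps the maximum of a pure-noise bin far below the
3-sigma threshold, so empty bins are essentially never "detected". The
report tabulates detected-bin counts per (cell count, NS) condition and
the fraction of adjacent condition steps with non-decreasing counts.

## 7. Problem sizes and reproducibility

The test suite and acceptance script run the full default titration
cohort (196 spectra of 32 768 points) for the detection-limit and
classification analyses; Monte-Carlo calibrations use 100–200 repeats
(CRS recovery, null-screen type-I error, SNR scaling) at full or
moderately reduced spectral resolution (8 192 points for the null
cohorts, where only integrated areas matter). All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence`; two runs
with the same configuration are bit-identical, and the pipeline manifest
(config echo, package version, seeds, QC exclusions) suffices to
reproduce a run.

## 8. Known limitations

* The CRS score follows the minimal reading of "mutual correlation of a
  metabolite's candidate bins"; with only two candidates the score
  cannot rank them (both share one correlation) and the median-intensity
  tie-break decides.
* The Bernstein baseline is fitted to anchors by least squares; an
  interactive tool's exact objective may differ. Anchor auto-detection
  assumes enough signal-free axis per segment.
* Classification validation follows the replicated-split scheme as
  specified; nested cross-validation or bootstrapping would give less
  optimistic component selection but is out of scope.
* JCAMP-DX support covers single-block real 1D records with AFFN or
  SQZ/DIF/DUP ordinates; compound and NTUPLES files are rejected with a
  clear message.
* Score and loading visualisation is left to downstream tools: the
  pipeline writes PCA scores/loadings and VIP rankings as delimited
  text rather than rendering plots, keeping the dependency surface to
  the numerical stack.
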