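# neutromet

A pipeline for untargeted 1D ¹H-NMR metabolomics of samples with **low
amounts of input material** — the regime of clinical neutrophil studies
where only 10⁵–10⁶ cells can be isolated and every spectrum sits close to
the detection limit. The package covers the full path from an acquired
spectrum to validated statistics:

1. **Spectral QC and correction** — chemical-shift referencing to the TSP
   internal standard at 0 ppm, line-width QC (FWHM of the reference peak
   < 1 Hz), Bernstein-polynomial baseline correction through 10–20
   baseline anchor points, exclusion of the residual-water region
   (4.40–5.00 ppm).
2. **Pattern-driven binning** — variable-width bins with left/right ppm
   boundaries per peak multiplet, trapezoidal integration.
3. **CRS filtering** — a correlation reliability score selects one
   representative bin per annotated metabolite (the candidate with the
   highest mean Pearson correlation to its sibling bins across samples)
   and removes unannotated bins.
4. **Statistics** — total-area (TA) normalisation, Pareto scaling, PCA,
   NIPALS PLS-DA with variable-importance-in-projection (VIP) scores,
   replicated stratified 70:30 validation with LOOCV component selection
   by balanced error rate (BER, computed from Mahalanobis distances in
   latent space), and a univariate screen (Student's *t* / ANOVA + Tukey
   HSD, Shapiro–Wilk reported, Benjamini–Hochberg FDR).
5. **Synthetic study generator** — simulates the cell-count ×
   number-of-scans (NS) titration design (100 k … 5 M cells; NS 256 …
   2048), so every stage is testable without instrument data.

## The model in brief

A spectrum is simulated as

```
I(δ) = Σ_m  s_m · c · r_m(c) · Σ_k A_mk L(δ; δ_mk + ε_m, γ_mk)
       + baseline(δ) + water(δ) + TSP(δ) + η(δ)
```

with `L` a unit-height Lorentzian, `c` the cell count, `s_m` the
per-cell signal of metabolite *m*, `r_m(c) = c⁴/(c⁴ + K_m⁴)` a sigmoidal
recovery term (labile metabolites vanish below a threshold cell count),
`ε_m ~ N(0, σ_shift)` per-metabolite chemical-shift jitter, and
`η ~ N(0, σ_ref·√(NS_ref/NS))` — so doubling the number of scans buys a
√2 gain in signal-to-noise ratio.

For classification, PLS-DA is NIPALS PLS2 on Pareto-scaled features
against a centred class-indicator matrix; a new sample is projected with
the rotation `W(PᵀW)⁻¹` and assigned to the class whose training-score
mean is nearest in Mahalanobis distance under the pooled, ridge-regularised
within-class score covariance. VIP scores satisfy `Σⱼ VIPⱼ² = p`.

## Worked example

Simulate a two-group cohort (group B has 2× lactate and 0.5× glutamate),
run preprocessing, binning, CRS filtering and the replicated validation:

```python
import neutromet as nm

syn = nm.SyntheticConfig(seed=42)
cohort = nm.two_group_cohort(syn, {"lactate": 2.0, "glutamate": 0.5}, n_per_group=12)
pattern = nm.default_pattern()
cfg = nm.PipelineConfig(timestamps=False)

passed, qc, failed = nm.preprocess_cohort(cohort, cfg, pattern)
table = nm.ta_normalise(nm.integrate_bins(passed, pattern))
filtered, crs = nm.crs_select(table, pattern)
report = nm.replicated_evaluation(filtered, list(filtered.sample_meta["group"]), seed=42)
print(report.aggregate.round(3))
print(report.vip_table().head(4).round(2).to_string(index=False))
```

prints

```
                   mean   sd
accuracy            1.0  0.0
balanced_accuracy   1.0  0.0
sensitivity         1.0  0.0
specificity         1.0  0.0
precision           1.0  0.0
f1                  1.0  0.0
ber                 0.0  0.0
     variable  vip_mean  vip_sd  vip_gt_1
    b_lac_thr      3.53    0.00      True
  b_lactate_1      2.19    0.00      True
b_glutamate_2      2.09    0.00      True
  b_taurine_1      0.73    0.01     False
```

CRS reduced 56 bins to 27 representative metabolite bins (9 unannotated
bins removed, 20 non-representative candidates dropped). The perturbed
metabolites top the VIP ranking — lactate through both its own bin and
the shared lactate/threonine bin — and the perfect aggregate accuracy
(mean ± SD over ten 70:30 replicates) reflects the strong planted
effect; a null cohort (`effect={}`) hovers at chance instead.

The same workflow is available from the shell:

```bash
neutromet run --config config.yaml --out results/
neutromet detect-limit --out detection_limit.tsv
```

`run` writes QC reports, feature tables, CRS results, PCA scores and
loadings, the validation report, VIP table, univariate screen, the
detection-limit table and a reproducibility manifest.

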