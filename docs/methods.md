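# Methods note

This note records the generative model, the numerical choices behind the
preprocessing and chemometrics, and the package's known limitations. All
problem sizes quoted here (cohort sizes, grid, LV ranges, CV rounds) are the
package's own defaults, chosen to be representative of longitudinal plasma
FTIR monitoring studies; every one is a plain parameter.

## Synthetic cohort model

Spectra live on a descending grid 4000 → 400 cm⁻¹ at 2 cm⁻¹ spacing
(1801 points). Each spectrum is

```
A(w) = B(w) + Σ_b  a_b · M_g(b) · exp(σ_pat z_pat,b) · exp(σ_rep z_rep,b) · L_b(w) + ε(w)
```

- `B(w)` — a fixed cubic polynomial in the reduced coordinate
  `x = (w − 2200)/1800`, giving a gentle, realistic scattering background.
- `L_b` — unit-height Gaussian `exp(−4 ln 2 · (w − c)² / fwhm²)` or
  Lorentzian line shapes for ~19 bands with literature-style assignments
  (amide I 1656, amide II 1545, CH₂/CH₃ stretches 2850–2960, carbohydrate
  and phosphate modes 1000–1200, the broad O–H envelope, …). Base
  amplitudes are scaled so amide I peaks near 0.70 AU, typical of dried
  plasma films measured in transmission.
- `M_g(b)` — the group effect: a per-band positive multiplier (1 for the
  reference group). Treatment presets perturb protein, lipid and saccharide
  bands by a few percent to tens of percent.
- Patient and replicate variation are log-normal per band with relative SDs
  `σ_pat = 0.08` and `σ_rep = 0.03`. Log-normal keeps amplitudes positive
  and makes the patient level dominate, matching the common observation that
  between-patient spread exceeds replicate spread by roughly 3×.
- `ε` — white Gaussian noise, SD 0.002 AU, consistent with the
  signal-to-noise of averaged FTIR scans.

These four noise/scale defaults were fixed once from the above physical
reasoning, before any classifier results were inspected, and are not tuned.

The default monitoring design has five groups (baseline, post-hormone,
post-radiotherapy, 2-month, 8-month) of 37/36/43/37/35 patients with 10
replicate spectra each; the toxicity design compares 24 vs 19 (acute) and
24 vs 11 (late) patients. All randomness flows from a single integer seed
through `numpy.random.default_rng`.

## Preprocessing

1. **Quality tests.** Amide-I signal level within [0.35, 1.25] AU
   (1600–1700 cm⁻¹ max), spectral SNR ≥ 10 (noise estimated in the
   band-free 1800–1900 cm⁻¹ window), and water-vapour contamination
   (1837–1847 cm⁻¹ peak-to-peak) below 0.05 AU. Failures are logged with
   the failing criterion and excluded.
2. **Truncation** to 800–4000 cm⁻¹ (1601 points).
3. **Rubberband baseline.** The baseline is the lower convex hull of the
   (wavenumber, absorbance) points, computed with Andrew's monotone-chain
   algorithm in O(n) after the grid sort. The hull is the pointwise maximum
   over all chords that lie nowhere above the spectrum; tests pin the fast
   implementation to a brute-force O(n³) chord oracle at 1e−10. This
   primitive is hand-written because it is the analytical core of the
   protocol; everything standard around it (filters, tests, factorisations)
   uses scipy/scikit-learn.
4. **Second derivative.** Savitzky–Golay, default window 9, polynomial
   order 3, `scipy.signal.savgol_filter(..., deriv=2, delta=2.0,
   mode="interp")`. SG differentiation is exact on polynomials up to the
   fit order but attenuates sinusoids: for spatial frequency k and half
   width m the response factor is `−Σ_j c_j cos(j k h) / k²`. At the sine
   used in the tests (k = 0.05 rad · cm, h = 2 cm⁻¹) the factor is
   0.9863810 for window 9 (1.36% amplitude bias) and 0.99205 for window 7
   (0.80%). Tests freeze the exact window-9 attenuation; the "within 1%"
   sine check is run at window 7, where it genuinely holds.
5. **Analysis range, then normalisation.** The derivative spectra are
   restricted to 3500–1000 cm⁻¹ (1251 points) and only then vector
   normalised, so the final vectors have exactly unit Euclidean norm — the
   contract downstream code relies on. The default dialect subtracts the
   mean before scaling (offset- and scale-invariant); a pure unit-norm
   dialect is available.

A parallel "absorbance" branch (baseline-corrected, normalised, without
differentiation) is kept for difference spectra, where band signs are
interpretable.

## Group statistics

Difference spectra are computed between groups of patient-mean spectra
(replicates averaged first, so patients are the independent units). Each
grid point gets a two-tailed Welch t-test; the significance map is
p < 0.001 with no multiple-testing correction by default — the map is
descriptive, localising where groups differ, not a confirmatory test.
Benjamini–Hochberg correction is available as an option. Calibration tests
confirm the empirical type-I fraction matches 0.001 within binomial error.

## Chemometrics

**PCA** uses the full SVD on mean-centred patient-mean spectra; explained
variances are pinned to a direct covariance eigendecomposition. Scores
plots carry 95% confidence ellipses with semi-axes
`sqrt(χ²₂(0.95) · eigenvalues)` of the 2-D score covariance
(radius ≈ 2.4477 under unit covariance); Monte-Carlo tests confirm 95 ± 1%
coverage.

**PLS-DA** is PLS1 regression (NIPALS, no column scaling) on a 0/1 class
vector, thresholded at 0.5. Two verified algebraic properties shape the
implementation: at `n_lv = rank(X)` PLS predictions equal minimum-norm
least squares, and NIPALS components are nested, so the k-component
coefficient vector is `x_rotations[:, :k] @ y_loadings[:k]` from a single
fit at the maximum LV count.

**Cross-validation protocol.** 20 rounds; in each round 10% of patients
*per group* (at least one) are held out, the model is fitted once at the
maximum LV count (default 50) on the training patients' spectra, and the
nested-coefficient identity evaluates every 1 ≤ m ≤ 50 on the held-out
patients' spectra. Splits are patient-disjoint by construction and recorded
in the results. Sensitivity (positive class = second group) and specificity
are averaged over rounds per m; the reported model is the smallest m
maximising balanced accuracy. The single-fit trick makes the full sweep
(50 LVs × 20 rounds × 4 comparisons on ~700 training spectra of 1251
points) run in seconds.

## Pipeline determinism

`run_pipeline` derives every stage seed from the run seed
(`(seed·1000003 + 7919·(i+1)) mod 2³¹`), writes all tables as CSV with
fixed float formatting and no timestamps, regenerates `report.md` purely
from the CSVs, and emits a SHA-256 manifest. Rerunning with the same config
and seed is byte-identical; this is asserted in tests.

## Calibration findings and limitations

- **Null-CV calibration.** With 3 held-out patients per class and 20
  rounds, each per-LV mean sensitivity/specificity rests on 60 Bernoulli
  draws → SE ≈ 6.5 percentage points. A requirement that every per-LV mean
  lie within 50 ± 5 on a null cohort is therefore violated with high
  probability by *any* unbiased protocol; the corresponding test is kept as
  stated and currently fails at a 5.3-point maximum deviation (30 + 30
  patients, seed 0). The protocol's grand-mean balanced accuracy over all
  LVs and 10 seeds is 50.4 ± 1.1 — unbiased. Tightening would require more
  rounds or larger held-out sets, which changes the protocol itself.
- **Signal recovery.** A two-band effect of 5× the patient-level relative
  SD (multiplier 1.40 on amide I and the 2930 cm⁻¹ CH₂ band, 24 vs 19
  patients) is recovered at ≥ 95% best sensitivity and specificity, with
  balanced accuracy strictly increasing along a 0/1/2/5× effect ladder.
- The generator is a band-multiplier model: it does not simulate scattering
  artefacts (Mie), water-vapour line structure beyond a QC surrogate, or
  correlated biochemical shifts across bands. Claims about the pipeline's
  robustness to those effects are out of scope.
- PLS-DA sensitivity/specificity are per-spectrum on held-out patients;
  per-patient majority voting is not implemented.
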