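# plasmaftir

Chemometrics pipeline for monitoring radiotherapy response from Fourier-transform
infrared (FTIR) spectra of blood plasma, with a hierarchical synthetic-cohort
generator for end-to-end validation.

FTIR spectroscopy of dried plasma films captures a broadband biochemical
fingerprint — protein amide bands, lipid CH stretches, carbohydrate and nucleic
acid modes — in a single cheap measurement. In longitudinal radiotherapy
studies, plasma is drawn from each patient at several time points (before
treatment, after neo-adjuvant hormone therapy, immediately after radiotherapy,
and at follow-ups) and the question is whether treatment leaves a detectable,
classifiable imprint on the spectrum. This package implements the full analysis
protocol for that question:

1. **Synthetic cohort generation** (`plasmaftir.cohort`) — a hierarchical
   generative model of plasma FTIR spectra: a smooth baseline plus ~19
   biochemically assigned Gaussian/Lorentzian bands, with log-normal
   patient-level and replicate-level amplitude variation, white detector
   noise, and group effects expressed as per-band intensity multipliers.
   Presets mirror a realistic study design: five time-point groups of 35–43
   patients with 10 replicate spectra each, and a toxicity design (24 vs 19
   and 24 vs 11 patients).
2. **Preprocessing** (`plasmaftir.preprocess`) — quality tests (signal level,
   signal-to-noise, water-vapour contamination), truncation to 800–4000 cm⁻¹,
   rubberband (lower convex hull) baseline correction, Savitzky–Golay second
   differentiation, restriction to the 3500–1000 cm⁻¹ analysis range, and
   vector normalisation.
3. **Group statistics** (`plasmaftir.group_statistics`) — difference spectra
   between patient-mean spectra with pointwise Welch t-tests (p < 0.001) and
   contiguous significant-region extraction with band assignment.
4. **Chemometrics** (`plasmaftir.chemometrics`) — PCA with 95% confidence
   ellipses, and PLS-DA with a repeated, patient-stratified cross-validation
   protocol: 20 rounds of 90/10 patient-level splits per group, sensitivity
   and specificity swept over 1–50 latent variables, and an automatic LV
   choice at maximal balanced accuracy.
5. **Pipeline + CLI** (`plasmaftir.pipeline`, `plasmaftir.cli`) — a
   deterministic end-to-end run driven by a YAML config, writing CSV tables,
   a Markdown report regenerable from the CSVs alone, and a SHA-256 manifest.

Model fitting follows the statsmodels convention: a model object is
constructed, `fit()` returns an immutable results object
(`PLSDA(...).fit() -> PLSDAResults`, and likewise for PCA).

## Worked example

```python
from plasmaftir import (
    treatment_monitoring_config, generate_cohort, preprocess_dataset,
    difference_spectrum, significant_regions, cross_validate,
)

config = treatment_monitoring_config(seed=7)
raw = generate_cohort(config)
print("spectra:", raw.data.shape, "groups:", sorted(set(raw.metadata["group"])))

multivariate, absorbance, qc = preprocess_dataset(raw)
print("passed QC:", multivariate.data.shape[0])

diff = difference_spectrum(absorbance, "baseline", "eight_month")
print("significant points (p<0.001):", int(diff.significant_mask.sum()),
      "of", diff.grid.size)
widest = max(significant_regions(diff), key=lambda r: r["hi"] - r["lo"])
print("widest region: %.0f-%.0f cm^-1" % (widest["lo"], widest["hi"]))

cv = cross_validate(multivariate, "baseline", "eight_month",
                    m_max=15, rounds=20, seed=7)
best = cv.table.loc[cv.table["lv"] == cv.chosen_m].iloc[0]
print("chosen LVs:", cv.chosen_m)
print("sensitivity %.1f +/- %.1f, specificity %.1f +/- %.1f" % (
    best["sensitivity_mean"], best["sensitivity_sd"],
    best["specificity_mean"], best["specificity_sd"]))
```

Output (deterministic for the seeds above):

```
spectra: (1880, 1801) groups: ['baseline', 'eight_month', 'post_hormone', 'post_radiotherapy', 'two_month']
passed QC: 1880
significant points (p<0.001): 1323 of 1601
widest region: 1772-2822 cm^-1
chosen LVs: 4
sensitivity 95.7 +/- 7.3, specificity 98.1 +/- 3.6
```

The baseline vs 8-month comparison carries a strong injected group effect, so
most of the truncated grid is pointwise significant and a 4-LV PLS-DA model
separates the groups with high sensitivity and specificity.

## Command-line interface

The `plasmaftir` command exposes each stage and a full pipeline run:

```bash
plasmaftir generate   --config cohort.yaml --seed 1 --out gen/
plasmaftir preprocess --data gen/data.csv --meta gen/metadata.csv --out pp/
plasmaftir diff  --data pp/absorbance.csv   --meta pp/absorbance_meta.csv   -a baseline -b eight_month --out diff.csv
plasmaftir pca   --data pp/multivariate.csv --meta pp/multivariate_meta.csv -a baseline -b eight_month --out pca/
plasmaftir plsda --data pp/multivariate.csv --meta pp/multivariate_meta.csv -a baseline -b eight_month --seed 2 --out cv.csv
plasmaftir run   --config run.yaml
```

Stages report errors as `error in stage <name>: ...` and exit non-zero.
`plasmaftir run` writes `report.md`, all CSV tables, `config.yaml` and a
`manifest.json` with SHA-256 checksums; reruns with the same config and seed
are byte-identical.

## Validation and reproduction

All numerical claims are pinned by tests against independent oracles: the
rubberband baseline against a brute-force chord search, Savitzky–Golay
derivatives against analytic polynomial/sine derivatives, PLS against
minimum-norm least squares, PCA against a direct covariance
eigendecomposition, the Welch t-test's type-I rate against its nominal level,
and the CV protocol against null and planted-signal cohorts.

```bash
python -m pytest -q tests/                                        # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script (~30 s) recomputes the headline quantities — oracle
deviations, calibration rates, ellipse coverage, null-CV calibration,
signal-recovery operating point, pipeline artifact counts, and a
byte-identity rerun flag — and writes them as JSON.

One known open point: the null-cohort CV calibration test asserts mean
sensitivity and specificity within 50 ± 5 at *every* LV count. With 3
held-out patients per class and 20 rounds each per-LV mean has a standard
error of ≈ 6.5 percentage points, so the maximum over LV counts exceeds the
band with high probability for any unbiased protocol; the test is kept as
stated and currently fails at a 5.3-point deviation. The protocol itself is
unbiased (grand-mean balanced accuracy 50.4 ± 1.1 across seeds). See
`docs/methods.md` for details.

## Layout

```
src/plasmaftir/   cohort, preprocess, group_statistics, chemometrics,
                  plot, pipeline, cli
tests/            unit + integration + acceptance tests with oracles
scripts/          acceptance.py
docs/methods.md   methods note: model, parameters, numerical choices
```
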