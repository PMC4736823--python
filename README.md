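# clickcyto

A quantification toolkit for click-chemistry nucleoside-incorporation
experiments (EdU / EdC labelling of replicating DNA), for researchers who
measure incorporation by fluorescence image cytometry, MTT viability
assays and chromatographic nucleoside analysis.

The package covers the full analysis chain:

* **Synthetic ground truth** — seeded generators for two-channel nucleus
  images, per-nucleus intensity tables, 4PL-shaped viability plates and
  nucleotide pool tables, all with known generating parameters.
* **Image cytometry** — DAPI-based nucleus segmentation (Otsu or fixed
  threshold, optional watershed splitting, area/border filters) and
  per-nucleus mean-intensity measurement.
* **The trimmed labelling statistic** — the core estimator.  From a sample
  of N nuclei, estimate the labelled fraction *F* from the signal
  histogram, then compute the specific signal as

      S = mean of the (F − δ)·N brightest nuclei
        − mean of the (1 − δ − F)·N dimmest nuclei,        δ = 0.1

  subtract the same statistic from an untreated control, form condition
  ratios with s.e.m. across experiments, and normalize panels to a
  reference condition (= 100%).  Trimming by the margin δ discards the
  ambiguous middle of the histogram, and the top-minus-bottom difference
  cancels any common additive background.
* **Dose-response** — four-parameter logistic fits
  R(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill) of viability plates
  on serial fivefold dilution designs, with 95% confidence intervals and
  right-censoring when no IC50 is identifiable in the tested range.
* **Nucleoside quantification** — relative molar amounts from HPLC peak
  areas and extinction coefficients (EdU at 289 nm, ε = 12 000
  l·mol⁻¹·cm⁻¹; natural deoxynucleosides at 260 nm), EdU:dT DNA-content
  ratios, detection-limit flags (one EdC per thousand dT), nucleotide
  pool percentage shares and phosphorylation-state ratios.

## Worked example

The `demo` subcommand runs the whole synthetic pipeline — render a scene,
segment and measure it, score three paired EdU/EdC experiments generated
with equal true signal, and fit a viability plate:

```sh
$ clickcyto demo --seed 0 --out-dir demo_out
recovered F = 0.750 (truth 0.750)
EdU/EdC ratio = 0.999 +/- 0.001 (truth 1.000)
IC50 = 0.820 uM (truth 0.800)
```

`recovered F` is the mean labelled fraction estimated from 10,000-nucleus
samples whose true fraction was 0.75; the EdU/EdC ratio tests that two
conditions generated with identical specific signal score as equal
(mean ± s.e.m. over three paired experiments); the IC50 is the 4PL fit of
one simulated plate whose generating midpoint was 0.8 µM.  Result CSVs and
a JSON run manifest land in `demo_out/`.

The same stages are available as a library:

```python
import clickcyto as cc

table = cc.generate_intensity_table(cc.SceneConfig(labelled_fraction=0.45, seed=1))
F = cc.estimate_labelled_fraction(table)          # -> 0.4502
result = cc.trimmed_specific_signal(table, F)     # specific_signal, n_top, n_bottom
```

## Command-line interface

`simulate-scene`, `simulate-plate`, `segment`, `measure`, `score`,
`ratio`, `ic50`, `quant-dna`, `quant-pools`, `demo` — see
`clickcyto <subcommand> --help`.  Configuration can come from a flat YAML
file (`--config`); CLI flags override file values.  Exit codes: 0 ok,
2 config error, 3 data error, 4 numerical failure.
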