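# rbcspec

Semi-quantitative vibrational-spectroscopy analysis of red blood cells:
FTIR–ATR and Raman marker-band ratio panels, second-derivative protein
secondary-structure ratios, ektacytometry elongation indices, and exact
nonparametric group comparison — driven by a synthetic cohort generator with
a retained ground truth so every stage is verifiable offline.

## What it does

- **spectra_io** — two-column and JCAMP-DX-like spectral tables, cohort
  manifests, deterministic CSV result tables. Wavenumber axes are
  canonicalized to ascending order on load.
- **preprocess** — modality-specific chains. Raman: cosmic-ray removal
  (modified z-score of the second difference, iterative replacement) →
  13-point Savitzky–Golay smoothing → rubberband (lower convex hull)
  baseline → vector normalization. FTIR: smoothing → optional first-order
  ATR penetration-depth correction → vector normalization over
  900–3600 cm⁻¹. Second derivatives via the SG derivative filter.
- **band_analysis** — trapezoidal marker-band integration over a built-in
  library of published windows (amide I/II, CH-stretch windows, PO₂⁻,
  CO-O-C, ester C=O; Raman C=O/C=C/CH def/Phe) and the biomarker ratio
  panel (total protein, phospholipid, acyl-chain shortening, unsaturation,
  cholesterol esters, esterified lipids) plus 1660/1650 and 1640/1650
  second-derivative secondary-structure ratios.
- **hemorheology** — EI = (L−W)/(L+W), EImax at the 20 Pa end of the shear
  sweep, CBC index derivation (MCV, MCH, MCHC).
- **group_stats** — Mann–Whitney U with an *exact* permutation p-value
  (subset-sum dynamic program over midranks, correct under ties; normal
  approximation with tie/continuity correction for larger samples),
  Shapiro–Wilk, box-plot summaries, significance stars.
- **synthetic** — two-group cohorts of FTIR/Raman spectra built from
  analytic band profiles with log-normal amplitude variation, programmed
  group effect multipliers, baselines, noise and cosmic-ray spikes; every
  spectrum keeps a noise-free twin and analytic band areas in a truth store.
  Also generates deformability sweeps and CBC tables.
- **cli** — `simulate`, `preprocess`, `panel`, `rheology`, `stats`, `run`.

## CLI

```sh
# synthetic cohort (spectra, manifest, truth store, config snapshot)
rbcspec simulate --seed 1 --out cohort/ --n-control 10 --n-treated 10

# full pipeline: simulate -> preprocess -> panel -> stats -> report bundle
rbcspec run --seed 1 --out report/ --n-control 10 --n-treated 10

# panel from an existing manifest of raw spectra
rbcspec panel --manifest cohort/manifest.csv --out panel/

# elongation-index analysis of a deformability table (sample_id, shear_Pa, L, W)
rbcspec rheology --table deformability.csv --out rheo/

# generic two-group comparison of a (group, value) table
rbcspec stats --table values.csv --out stats/
```

`run` writes `band_table.csv`, `panel_values.csv`, `panel_summaries.csv`
(median/IQR/min–max per group), `comparisons.csv` (U, exact p, stars) and a
`provenance.json` recording parameters and pipeline order. Reruns with the
same seed and config are byte-identical.

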