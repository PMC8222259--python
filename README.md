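# aortomorph

Quantitative aortic histomorphometry as a tested, fully synthetic-data-driven
pipeline:

- **`aortomorph.synth`** — seeded generators for stain-field images (Movat /
  Verhoeff / VVG / H&E palettes, wavy elastic lamellae, nuclei, fragmentation),
  annular vessel cross-sections, and two-group subject cohorts — all with
  exact ground truth recorded pre-noise.
- **`aortomorph.segmentation`** — nearest-prototype pixel classification in
  CIELAB with ΔE and luminance cutoffs; medial component area fractions.
- **`aortomorph.morphometry`** — lamella counting/thickness/spacing along
  transects with branch-point exclusion, H&E nuclei counting with
  deterministic overlap policies, radial layer-thickness measurement.
- **`aortomorph.aortometry`** — nomogram-based expected diameter, z-score and
  size classification, medial annulus cross-sectional area, per-cross-section
  component amounts and SMC counts.
- **`aortomorph.remodeling`** — area-conservation model of medial thinning
  under lumen dilatation (`b' = sqrt(a'^2 + 2ab + b^2) - a'`) and the inverse
  pre-dilatation prediction with uniform lamellar scaling.
- **`aortomorph.stats`** — Mann–Whitney (exact/asymptotic dispatch), the
  Freeman–Halton exact test for r×c tables by full fixed-margin enumeration,
  Kruskal–Wallis with Dunn's Bonferroni pairwise tests, tie-aware Spearman
  correlation and inter-rater agreement.
- **`aortomorph.pipeline`** — one-command orchestration
  (synth → segment → morph → derive → stats) with blinded measurement stages,
  seed fan-out, and a provenance-stamped report.

## CLI

```sh
aortomorph synth field --spec field.yaml --seed 3 --out field.png
aortomorph synth ring --seed 1 --out ring.png
aortomorph synth cohort --seed 1 --out cohort.csv
aortomorph segment --image field.png --out fractions.csv
aortomorph morph lamellae --image field.png --out lamellae.csv
aortomorph morph nuclei --image he.png --out nuclei.csv
aortomorph morph layers --image ring.png --out layers.csv
aortomorph derive --subjects cohort.csv --morph morph.csv --out derived.csv
aortomorph remodel curve --index 10 --index 20 --out curve.csv
aortomorph stats fisher --table counts.csv
aortomorph run --config run.yaml --seed 7 --out report_dir
```

Images carry a `<name>.<ext>.json` sidecar with pixel size, stain kind, seed,
and generator truth; palettes and run configuration are YAML; all tables are
headered CSV.

The nomogram ships with clearly synthetic default coefficients; supply real
published regression coefficients via `--nomogram nomo.yaml`
(`{intercept, coef_age, coef_sex, coef_bsa, residual_sd}`) for real use.

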