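# lipidens

Untargeted LC-MS lipidomics case-control analysis as a tested, reusable
pipeline:

* **Filtering** — features are kept only when their mean study intensity is
  ≥ 1.5-fold above reagent blanks and their pooled-QC coefficient of
  variation is ≤ 30%.
* **Normalization** — natural-log transform, per-feature OLS removal of
  batch and gel-status artifacts, and upper-quantile (75th percentile)
  scaling.
* **Ensemble variable selection** — the intersection of three criteria:
  top 1% by case-control linear-model p-value, bootstrap-LASSO stability
  selection (≥ 10% selection frequency over 500 bootstrap replicates along
  a descending penalty grid), and top 1% by random-forest out-of-bag
  permutation importance; an exclusion loop stands in for manual
  peak-morphology review.
* **Time-to-diagnosis (ttd) classification** — each selected feature's
  pair-level log fold-change is regressed on ttd; flat trajectories are
  potentially causal (C), shrinking case-control differences are reactive
  (R, reverse causality), growing differences are indeterminate (I).
* **Mass tools** — monoisotopic masses from molecular formulas,
  [M−H]⁻ / [M+HAc−H]⁻ adduct m/z, Δppm, neutral-loss assignment of MS2
  fragments, and Pearson-correlation feature clustering.
* **Synthetic cohorts** — a first-class generator of matched case-control
  cohorts with planted causal/reactive/indeterminate effects, batch and
  gel artifacts, QC injections, and reagent blanks, used for parameter
  recovery and calibration tests.

## Command line

```bash
# generate a synthetic fixture
lipidens simulate --out fixture/ --pairs 66 --features 2000 --seed 1

# individual stages
lipidens filter    --features fixture/features.tsv --samples fixture/samples.tsv --out out/
lipidens normalize --features fixture/features.tsv --samples fixture/samples.tsv --out out/normalized.tsv
lipidens select    --features fixture/features.tsv --samples fixture/samples.tsv \
                   --boot 500 --grid-size 50 --freq-cut 0.10 --top-frac 0.01 --seed 1
lipidens classify  --normalized out/normalized.tsv --samples fixture/samples.tsv
lipidens annotate  --table annotations_in.tsv

# full pipeline (config.toml holds PipelineConfig fields)
lipidens run --config config.toml --seed 1 --out results/
```

The pipeline writes a deterministic bundle: `filter_report.tsv`,
`normalized.tsv`, `selection.tsv`, `ttd_classes.tsv`, `volcano.tsv`,
`cohort_table.tsv` and `report.json` (stage counts, parameters, selected
features, C/R/I labels, in-sample classification rates).

## Data formats

* `features.tsv` — `feature_id`, `mz`, `rt_sec`, then one intensity column
  per sample id.
* `samples.tsv` — `sample_id`, `role∈{study,qc,blank}`, `pair_id`,
  `caco∈{case,control,NA}`, `gel∈{0,1}`, `batch∈{1,2}`, `age`,
  `gender∈{M,F}`, `ttd_years`, plus optional covariate columns.
* `truth.tsv` (synthetic fixtures) — per-feature planted effect type and
  parameters.

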