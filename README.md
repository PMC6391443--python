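# droughtlegacy

Drought response, lag and legacy-effect analysis for gridded terrestrial
biosphere model (TBM) output — with a seeded synthetic pseudo-model
ensemble so the entire chain is testable against known truth.

## The scientific problem

Process-based land carbon models must get drought *recovery* right, not
just drought response: if modeled productivity rebounds the year after a
drought while real forests stay depressed for years, models will
overestimate the future land carbon sink. Tree-ring studies indicate that
forest growth remains roughly 9% below its climate-expected value in the
first year after an extreme drought, while model ensembles typically show
a ~2% depression that vanishes by year 2 — legacies about four times
weaker and four times shorter than observed.

This package implements the analysis chain used to make that comparison,
for anyone evaluating TBM or pseudo-model NPP output against
drought-recovery benchmarks:

1. **Drought detection** — climatic water deficit CWD = P − PET
   (mm month⁻¹), annual totals Z-scored per 0.5° cell; extreme drought at
   Z ≤ −2, climate-normal years at −1 ≤ Z ≤ 1. Consecutive extreme years
   merge into one event anchored at its last year; events followed by
   another extreme drought within 4 years are excluded.
2. **Lag mapping** — per cell, 61 Pearson correlations between monthly
   de-seasonalized CWD and NPP anomalies at offsets of 0–60 months;
   r_max is the moisture sensitivity, its offset the lag time, with
   Benjamini–Hochberg FDR control across each model's map and lag bins
   {0, 1, 2, 3–6, 7–12, 13–24, >24} months.
3. **Recovery trajectories** — 5-year anomaly sets (drought year + 4)
   under two baselines: the climate-normal mean NPP (absolute,
   gC m⁻² yr⁻¹, integrable to PgC with spherical cell areas) and per-cell
   OLS of annual NPP on annual CWD (percent of expected NPP, restricted to
   cells with significant r > 0.3), averaged over events within — never
   across — cells, stratifiable by dominant forest type.
4. **Ensemble synthesis** — per-model spatial means, percentile bootstrap
   (n = 5000) CIs of the ensemble mean, percentile bands across models,
   and a year-by-year weakness/duration comparison against a tree-ring
   benchmark (year-1 depression 9%).

The synthetic generator injects a known response lag, sensitivity,
drought-year depression and 4-year legacy profile into AR(1)-noised
pseudo-model NPP, so every stage can be validated by parameter recovery.

## Worked example

`examples/05_ensemble_vs_benchmark.py` runs the full pipeline on 12
pseudo-models whose true legacy is a 2% year-1 depression, against the 9%
tree-ring benchmark:

```
ensemble mean percent anomaly (drought year .. +4), with 95% bootstrap CI:
  year 0: -4.80%  [-4.89, -4.73]
  year 1: -1.68%  [-1.75, -1.60]
  year 2: +0.19%  [+0.10, +0.29]
  ...
benchmark comparison (post-drought years):
 post_drought_year  modeled_depression_pct  observed_depression_pct  weakness_ratio
                 1                    1.68                      9.0            5.36
                 2                   -0.19                      5.0             NaN
modeled legacy lasts 1 year(s) vs 3 in the benchmark
```

Year 0 is the drought year itself (depression relative to CWD-expected
NPP); post-drought year 1 shows the modeled legacy at roughly one fifth to
one quarter of the benchmark, gone by year 2 — the characteristic
"too weak, too short" model signature. The other example scripts walk
through generation, detection, lag mapping and trajectory construction
individually, each printing the injected truth beside the recovered value.

A thin CLI wraps the same pipeline:

```bash
droughtlegacy synth --out data/ --seed 5          # NetCDF + truth sidecar
droughtlegacy run --config cfg.yaml --out report/ # full analysis + manifest
```

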