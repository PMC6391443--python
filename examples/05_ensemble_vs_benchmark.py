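"""Full pipeline: 12 pseudo-models against the tree-ring benchmark.

The ensemble is generated with a deliberately weak, short legacy (2% in
post-drought year 1, nothing after) while the benchmark says growth should
be 9% below expectation in year 1 — the configuration that reproduces the
qualitative finding that modeled drought legacies are roughly four times
weaker and shorter than tree rings suggest.
"""

from droughtlegacy import PipelineConfig, SyntheticConfig, run_pipeline

cfg = PipelineConfig(
    synthetic=SyntheticConfig(
        n_lat=10, n_lon=10, n_models=12,
        legacy_profile=(0.02, 0.0, 0.0, 0.0),
        drought_year_depression=0.06,
        response_lag_months=0,
        seed=9,
    ),
    n_boot=5000,
    seed=9,
)
result = run_pipeline(cfg)

s = result.summary
print("ensemble mean percent anomaly (drought year .. +4), with 95% bootstrap CI:")
for k in range(5):
    print(f"  year {k}: {s.mean[k]:+.2f}%  [{s.ci_low[k]:+.2f}, {s.ci_high[k]:+.2f}]")

print("\nmodel spread (25th/50th/75th percentile, year 1):",
      ", ".join(f"{v:+.2f}%" for v in result.percentiles[:, 1]))

table = result.comparison
print("\nbenchmark comparison (post-drought years):")
print(table.to_string(index=False))
print(f"\nmodeled legacy lasts {table.attrs['modeled_duration_years']} year(s) vs "
      f"{table.attrs['observed_duration_years']} in the benchmark; the year-1 "
      "weakness ratio near 4 mirrors the observed model-vs-tree-ring gap")
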