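"""One-call end-to-end run: the default 21-patient preset.

Simulates the full two-panel cohort (20 fields per panel per patient),
computes the complete metric catalogue, all Mann-Whitney group comparisons,
correlations and survival stratifications, and writes the TSV report
bundle. Takes a few seconds.
"""

from immunocontexture import default_config, generate_report, run_pipeline

cfg = default_config(seed=0, output_dir="example_report")
bundle = run_pipeline(cfg)
out = generate_report(bundle, cfg.output_dir)

print(f"patients analyzed: {bundle.n_patients}")
print(f"metrics per patient: {bundle.metric_wide.shape[1]}")
print(f"group comparisons: {len(bundle.group_comparisons)}")
print(f"survival stratifications: {len(bundle.survival_table)}")
print(f"report written to: {out}/")
print()
sig = bundle.group_comparisons[bundle.group_comparisons["p"] <= 0.05]
print(f"{len(sig)} comparisons reach p <= 0.05; the CD-vs-PD contrasts in")
print("cytotoxic and regulatory T-cell metrics reflect the simulated group")
print("profiles, e.g.:")
for r in sig[sig["grouping"] == "dcr_group"].head(5).itertuples(index=False):
    print(f"  {r.metric}: median {r.median1:.2f} (CD) vs {r.median2:.2f} (PD), p={r.p:.4f}")
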