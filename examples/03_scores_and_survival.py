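"""Prognostic scores and survival stratification on a synthetic cohort.

Runs the cohort simulator, computes the four Immunoscore input densities,
derives the I0/IntI/I4 classes and a median-split Kaplan-Meier / log-rank /
Cox analysis of the %CD8+GrzB+ metric.
"""

import dataclasses

from immunocontexture import (
    DEFAULT_PANELS,
    assign_phenotypes,
    compartment_density,
    compute_immunoscore,
    cox_hazard_ratio,
    default_simulation_config,
    dichotomize_by_median,
    kaplan_meier,
    logrank_test,
    phenotype_percentage,
    simulate_cohort,
)

cfg = dataclasses.replace(
    default_simulation_config(seed=4), n_patients=12, n_fields_per_patient=6,
    response_counts=None,
)
samples, survival, _ = simulate_cohort(cfg)
for s in samples:
    s.fields = [assign_phenotypes(f, DEFAULT_PANELS[f.panel_id]) for f in s.fields]

dens = {
    name: {
        s.patient_id: compartment_density(s, phen, comp).value for s in samples
    }
    for name, (phen, comp) in {
        "cd3_tumor": ("CD3", "tumor"),
        "cd3_stroma": ("CD3", "stroma"),
        "cd8_tumor": ("CD8", "tumor"),
        "cd8_stroma": ("CD8", "stroma"),
    }.items()
}
iscore = compute_immunoscore(**dens)
print("patient  score  class")
for pid, r in sorted(iscore.items()):
    print(f"{pid:7s}  {r.score:5d}  {r.immunoscore_class}")

pct = {
    s.patient_id: phenotype_percentage(s, "CD8_GrzB", "CD8", "total").value
    for s in samples
}
labels, rule = dichotomize_by_median(pct, metric="pct CD8+GrzB+ among CD8+")
by_pid = {r.patient_id: r for r in survival}
hi = [by_pid[p] for p in sorted(labels) if labels[p] == "high"]
lo = [by_pid[p] for p in sorted(labels) if labels[p] == "low"]
lr = logrank_test(hi, lo)
cox = cox_hazard_ratio(hi + lo, [1.0] * len(hi) + [0.0] * len(lo))
km_hi, km_lo = kaplan_meier(hi), kaplan_meier(lo)

print()
print(f"median %CD8+GrzB+ cutoff: {rule.median:.1f}% "
      f"(high n={len(hi)}, low n={len(lo)})")
def _fmt(m):
    return f"{m:.1f}" if m is not None else "not reached"

print(f"median OS high: {_fmt(km_hi.median)}, low: {_fmt(km_lo.median)} months")
print(f"log-rank chi2={lr.chi2:.2f}, p={lr.p:.3f}")
print(f"Cox HR (high vs low) = {cox.hr:.2f} "
      f"(95% CI {cox.ci_low:.2f}-{cox.ci_high:.2f})")
print()
print("An HR below 1 would mean the above-median activated-CTL group dies")
print("at a lower rate; at n=12 the interval is wide and the point estimate")
print("is dominated by sampling noise — the full preset uses 21 patients.")
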