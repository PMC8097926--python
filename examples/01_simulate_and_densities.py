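"""Simulate a small two-panel cohort and compute compartment densities.

Builds a 4-patient synthetic cohort, assigns phenotype labels from marker
combinations and prints per-patient intra-tumoral densities next to the
configured ground-truth intensities.
"""

import dataclasses

from immunocontexture import (
    DEFAULT_PANELS,
    assign_phenotypes,
    compartment_density,
    default_simulation_config,
    simulate_cohort,
)

cfg = dataclasses.replace(
    default_simulation_config(seed=1), n_patients=4, n_fields_per_patient=5,
    response_counts=None,
)
samples, survival, truth = simulate_cohort(cfg)

print("intra-tumoral densities (cells/mm²), estimate vs configured λ:")
print("patient   CD4 est   CD4 λ   CD8 est   CD8 λ")
for sample in samples:
    sample.fields = [assign_phenotypes(f, DEFAULT_PANELS[f.panel_id]) for f in sample.fields]
    cd4 = compartment_density(sample, "CD4", "tumor")
    cd8 = compartment_density(sample, "CD8", "tumor")
    l4 = truth.expected_density(sample.patient_id, "panel2", "CD4", "tumor")
    l8 = truth.expected_density(sample.patient_id, "panel2", "CD8", "tumor")
    print(f"{sample.patient_id:7s}  {cd4.value:8.1f}  {l4:6.1f}  {cd8.value:8.1f}  {l8:6.1f}")

print()
print("CD4 cells are placed by a plain Poisson process, so their estimate")
print("fluctuates around the configured intensity. CD8 cells additionally")
print("carry a proximity layer (30% re-placed within 20 µm of a tumor cell),")
print("which pulls them into the tumor compartment: their intra-tumoral")
print("density deliberately exceeds the nominal λ — attraction and density")
print("are coupled, exactly as tumor-infiltrating T cells behave.")
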