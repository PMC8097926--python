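"""Cell-to-cell proximity: nearest-neighbor distance and fraction-within.

Simulates one field in which 60% of CD8 cells are deliberately placed
within 15 µm of a tumor cell, then measures both proximity statistics and
shows how the fraction-within recovers the constructed attraction.
"""

from immunocontexture import (
    PANEL2,
    ProximityPlacement,
    SimulationConfig,
    assign_phenotypes,
    fraction_within_radius,
    nearest_neighbor_mean_distance,
    simulate_field,
)

cfg = SimulationConfig(
    intensities={"panel2": {"tumor": (0.0, 30.0), "CD8": (0.0, 400.0)}},
    tumor_nest_count=0,
    proximity_spec=[ProximityPlacement("CD8", "tumor", 0.6, 15.0, "panel2")],
    seed=2,
)
field = assign_phenotypes(simulate_field(cfg, seed=2, panel_id="panel2"), PANEL2)

nn = nearest_neighbor_mean_distance(field, "tumor", "CD8")
print(f"mean distance from each tumor cell to the nearest CD8+ cell: {nn:.1f} µm")
for radius in (10, 15, 20, 30):
    frac = fraction_within_radius(field, "CD8", "tumor", radius)
    print(f"% of CD8+ cells with a tumor cell within {radius:2d} µm: {frac:5.1f}%")

print()
print("At the 15 µm placement radius the fraction fluctuates around the")
print("constructed 60% attraction (plus a small chance-proximity background")
print("and binomial noise); it is non-decreasing in the radius by definition.")
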