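"""Synthetic cohort generator: geometry, Poisson placement, proximity
construction, survival layer and reproducibility."""

import math

import numpy as np
import pytest

from immunocontexture import (
    ConfigError,
    PANEL2,
    ProximityPlacement,
    SimulationConfig,
    SurvivalSpec,
    assign_phenotypes,
    fraction_within_radius,
    kaplan_meier,
    simulate_cohort,
    simulate_field,
)
from immunocontexture.io import STROMA, TUMOR


def base_config(**kw):
    defaults = dict(
        intensities={"panel2": {"tumor": (500.0, 0.0), "CD8": (100.0, 150.0)}},
        n_patients=2,
        n_fields_per_patient=1,
        tumor_nest_count=2,
        tumor_nest_radius_um=120.0,
        seed=7,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_zero_tumor_intensity_places_no_tumor_compartment_cells():
    cfg = base_config(
        intensities={"panel2": {"CD8": (0.0, 200.0)}}, tumor_nest_count=1
    )
    f = simulate_field(cfg, seed=1, panel_id="panel2")
    assert all(c.compartment == STROMA for c in f.cells)
    assert f.compartment_areas[TUMOR] > 0  # nest exists, it is just empty


def test_field_is_reproducible_for_fixed_seed():
    cfg = base_config()
    f1 = simulate_field(cfg, seed=11, panel_id="panel2")
    f2 = simulate_field(cfg, seed=11, panel_id="panel2")
    assert [(c.cell_id, c.x_um, c.y_um, c.compartment) for c in f1.cells] == [
        (c.cell_id, c.x_um, c.y_um, c.compartment) for c in f2.cells
    ]
    f3 = simulate_field(cfg, seed=12, panel_id="panel2")
    assert [(c.x_um, c.y_um) for c in f3.cells] != [(c.x_um, c.y_um) for c in f1.cells]


def test_poisson_mean_count_matches_configured_intensity():
    """lambda = 100 cells/mm² on a ~1 mm² nest: over 200 replicate fields the
    mean tumor-compartment count must sit within 3 SE of lambda * area."""
    radius = math.sqrt(1e6 / math.pi)  # disc area 1 mm²
    cfg = SimulationConfig(
        intensities={"panel2": {"CD8": (100.0, 0.0)}},
        tumor_nest_count=1,
        tumor_nest_radius_um=radius,
        tumor_nest_centers=[(650.0, 650.0)],
        field_width_um=1300.0,
        field_height_um=1300.0,
        seed=0,
    )
    counts = []
    area = None
    for seed in range(200):
        f = simulate_field(cfg, seed=seed, panel_id="panel2")
        counts.append(sum(c.compartment == TUMOR for c in f.cells))
        area = f.compartment_areas[TUMOR]
    expected = 100.0 * area  # rasterized area is the exact placement measure
    se = math.sqrt(expected) / math.sqrt(200)
    assert abs(np.mean(counts) - expected) < 3 * se


def test_realized_density_is_unbiased_for_recorded_area():
    cfg = base_config(tumor_nest_count=3)
    dens = []
    for seed in range(150):
        f = simulate_field(cfg, seed=seed, panel_id="panel2")
        n = sum(c.compartment == STROMA and not c.markers["melanoma"] for c in f.cells)
        dens.append(n / f.compartment_areas[STROMA])
    # lambda=150 in stroma; SE of the mean density over replicates
    se = np.std(dens, ddof=1) / math.sqrt(len(dens))
    assert abs(np.mean(dens) - 150.0) < 3 * se


def test_attracted_fraction_one_forces_full_proximity():
    cfg = base_config(
        intensities={
            "panel2": {"tumor": (300.0, 5.0), "CD8": (0.0, 120.0)}
        },
        proximity_spec=[ProximityPlacement("CD8", "tumor", 1.0, 20.0, "panel2")],
    )
    f = assign_phenotypes(simulate_field(cfg, seed=5, panel_id="panel2"), PANEL2)
    assert fraction_within_radius(f, "CD8", "tumor", 20.0) == 100.0


def test_proximity_spec_with_unknown_archetype_rejected():
    with pytest.raises(ConfigError, match="absent from"):
        base_config(
            proximity_spec=[ProximityPlacement("CD20", "tumor", 0.5, 20.0, "panel2")]
        ).validate()


def test_negative_intensity_rejected():
    with pytest.raises(ConfigError, match="negative intensity"):
        base_config(intensities={"panel2": {"CD8": (-1.0, 0.0)}}).validate()


def test_censoring_rate_boundary():
    SurvivalSpec(censoring_rate=0.999)  # accepted
    with pytest.raises(ConfigError):
        SurvivalSpec(censoring_rate=1.0)
    with pytest.raises(ConfigError):
        SurvivalSpec(baseline_hazard=0.0)


def test_cohort_is_reproducible_and_carries_ground_truth():
    cfg = base_config(n_patients=4, seed=42)
    s1, v1, t1 = simulate_cohort(cfg)
    s2, v2, t2 = simulate_cohort(cfg)
    assert [(r.patient_id, r.time, r.event) for r in v1] == [
        (r.patient_id, r.time, r.event) for r in v2
    ]
    for a, b in zip(s1, s2):
        for fa, fb in zip(a.fields, b.fields):
            assert [(c.x_um, c.y_um) for c in fa.cells] == [
                (c.x_um, c.y_um) for c in fb.cells
            ]
    assert t1.patient_ids == [s.patient_id for s in s1]
    assert t1.expected_density("P01", "panel2", "CD8", STROMA) == 150.0


def test_cohort_response_counts_and_group_sizes():
    cfg = base_config(
        n_patients=21,
        response_counts={"PD": 7, "SD": 7, "PR": 6, "CR": 1},
        seed=3,
    )
    _, survival, truth = simulate_cohort(cfg)
    dcr = [r.groups["dcr_group"] for r in survival]
    assert dcr.count("CD") == 14 and dcr.count("PD") == 7
    sites = [r.groups["site"] for r in survival]
    assert sites.count("liver") == 17 and sites.count("extra_hepatic") == 4


def test_exponential_survival_recovers_closed_form_median():
    """All coefficients zero, no censoring: KM median over n=500 must land
    within 10% of ln 2 / baseline hazard."""
    cfg = base_config(
        n_patients=500,
        intensities={"panel2": {"CD8": (0.0, 30.0)}},
        tumor_nest_count=0,
        survival=SurvivalSpec(
            baseline_hazard=1.0 / 24.0, censoring_rate=0.0, horizon_months=None
        ),
        seed=9,
    )
    _, survival, _ = simulate_cohort(cfg)
    assert all(r.event for r in survival)
    km = kaplan_meier(survival)
    assert km.median == pytest.approx(24.0 * math.log(2.0), rel=0.10)


def test_nonpositive_baseline_hazard_rejected_in_cohort():
    with pytest.raises(ConfigError):
        base_config(survival=SurvivalSpec(baseline_hazard=-0.1))
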