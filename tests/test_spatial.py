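"""Proximity metrics versus the brute-force oracle and their invariances."""

import math

import numpy as np
import pytest

from immunocontexture import (
    ProximityMetricSpec,
    aggregate_spatial_metric,
    fraction_within_radius,
    nearest_neighbor_mean_distance,
)

from conftest import (
    brute_fraction_within,
    brute_nn_mean,
    make_cell,
    make_field,
    make_sample,
    random_phenotype_field,
)


def field_of(points):
    """points: list of (id, x, y, labels)."""
    return make_field(
        [make_cell(i, x, y, phenotypes=frozenset(ls)) for i, x, y, ls in points]
    )


def test_nn_three_four_five_triangle():
    f = field_of([("r", 0, 0, {"A"}), ("t", 3, 4, {"B"})])
    assert nearest_neighbor_mean_distance(f, "A", "B") == 5.0


def test_nn_mean_over_references():
    f = field_of(
        [
            ("r1", 0, 0, {"A"}),
            ("r2", 10, 0, {"A"}),
            ("t1", 0, 1, {"B"}),
            ("t2", 14, 3, {"B"}),
        ]
    )
    # brute force over all 4 pairs: nearest distances are 1.0 and 5.0
    assert nearest_neighbor_mean_distance(f, "A", "B") == pytest.approx(3.0)


def test_nn_self_exclusion_single_cell_excludes_field():
    f = field_of([("only", 5, 5, {"A"})])
    assert nearest_neighbor_mean_distance(f, "A", "A") is None


def test_fraction_within_boundary_is_inclusive():
    f = field_of([("r", 0, 0, {"A"}), ("t", 0, 25, {"B"})])
    assert fraction_within_radius(f, "A", "B", 25.0) == 100.0


def test_fraction_within_counts_references_with_a_neighbor():
    f = field_of(
        [
            ("r1", 0, 0, {"A"}),
            ("r2", 50, 0, {"A"}),
            ("r3", 100, 0, {"A"}),
            ("t", 0, 10, {"B"}),
        ]
    )
    assert fraction_within_radius(f, "A", "B", 20.0) == pytest.approx(100.0 / 3.0)


def test_fraction_within_no_targets_is_zero_not_excluded():
    f = field_of([("r", 0, 0, {"A"})])
    assert fraction_within_radius(f, "A", "B", 20.0) == 0.0


def test_exact_agreement_with_brute_force_oracle(rng):
    """KD-tree implementation must agree bit-for-bit with the O(n·m) scan
    on >= 100 random fields of <= 500 cells, overlapping phenotypes included."""
    for _ in range(100):
        f = random_phenotype_field(rng, n_max=500)
        for ref, tgt in (("A", "B"), ("A", "A")):
            assert nearest_neighbor_mean_distance(f, ref, tgt) == brute_nn_mean(f, ref, tgt)
            radius = float(rng.uniform(5, 60))
            assert fraction_within_radius(f, ref, tgt, radius) == brute_fraction_within(
                f, ref, tgt, radius
            )


def test_fraction_within_monotone_in_radius(rng):
    f = random_phenotype_field(rng, n_max=300)
    vals = [fraction_within_radius(f, "A", "B", r) for r in (5, 10, 20, 40, 80, 160)]
    assert all(a <= b for a, b in zip(vals, vals[1:]))


def test_nn_invariant_under_rigid_motion(rng):
    f = random_phenotype_field(rng, n_max=200)
    base = nearest_neighbor_mean_distance(f, "A", "B")
    theta = 0.7
    c, s = math.cos(theta), math.sin(theta)
    moved = []
    for cell in f.cells:
        x, y = cell.x_um, cell.y_um
        moved.append(
            make_cell(
                cell.cell_id,
                c * x - s * y + 1000.0,
                s * x + c * y + 500.0,
                cell.compartment,
                phenotypes=cell.phenotypes,
            )
        )
    f2 = make_field(moved)
    assert nearest_neighbor_mean_distance(f2, "A", "B") == pytest.approx(base, rel=1e-12)


def test_adding_target_never_increases_any_nearest_distance(rng):
    f = random_phenotype_field(rng, n_max=200)
    base = nearest_neighbor_mean_distance(f, "A", "B")
    if base is None:
        pytest.skip("degenerate random draw with no A or B cells")
    extra = make_cell("extra", 300.0, 200.0, phenotypes=frozenset({"B"}))
    f2 = make_field(list(f.cells) + [extra])
    assert nearest_neighbor_mean_distance(f2, "A", "B") <= base


def test_patient_aggregation_means_and_tallies_exclusions():
    f1 = field_of([("r", 0, 0, {"A"}), ("t", 0, 10, {"B"})])
    f2 = field_of([("r", 0, 0, {"A"}), ("t", 0, 20, {"B"})])
    f3 = field_of([("t", 0, 0, {"B"})])  # no reference: excluded
    for f, fid in zip((f1, f2, f3), ("f1", "f2", "f3")):
        f.field_id = fid
    sample = make_sample([f1, f2, f3])
    res = aggregate_spatial_metric(
        sample, ProximityMetricSpec("nn_mean_distance", "A", "B")
    )
    assert res.patient_value == pytest.approx(15.0)
    assert res.n_fields_used == 2
    assert res.n_fields_excluded == 1

    res = aggregate_spatial_metric(
        sample, ProximityMetricSpec("fraction_within", "A", "B", radius_um=15.0)
    )
    assert res.patient_value == pytest.approx(50.0)  # fields at 100% and 0%
    assert res.n_fields_excluded == 1
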