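"""Phenotype rule application, density and percentage metrics."""

import math

import numpy as np
import pytest

from immunocontexture import (
    PANEL2,
    ValidationError,
    assign_phenotypes,
    compartment_density,
    patient_aggregate,
    phenotype_percentage,
)
from immunocontexture.io import STROMA, TUMOR

from conftest import make_cell, make_field, make_sample

P2_MARKERS = ("CD4", "CD8", "GranzymeB", "FoxP3", "CD163", "melanoma")


def cell_with(cid, positive, compartment=STROMA, x=0.0, y=0.0):
    markers = {m: (m in positive) for m in P2_MARKERS}
    return make_cell(cid, x, y, compartment, markers=markers)


def labeled_field(cells, **kw):
    return assign_phenotypes(make_field(cells, **kw), PANEL2)


@pytest.mark.parametrize(
    "positive,expected",
    [
        (("CD8", "GranzymeB"), {"CD8", "CD8_GrzB"}),
        (("CD4", "FoxP3"), {"CD4", "Treg"}),
        (("melanoma", "CD8"), {"tumor"}),  # tumor cocktail excludes immune labels
        (("CD4",), {"CD4"}),
        ((), set()),
    ],
)
def test_rule_application_is_multilabel_with_tumor_exclusion(positive, expected):
    f = labeled_field([cell_with("c1", positive)])
    assert set(f.cells[0].phenotypes) == expected


def test_rule_referencing_absent_marker_errors():
    cell = make_cell("c1", 0, 0, STROMA, markers={"CD8": True})  # no GranzymeB column
    with pytest.raises(ValidationError, match="absent"):
        assign_phenotypes(make_field([cell]), PANEL2)


def test_density_single_field():
    cells = [cell_with(f"c{i}", ("CD8",), TUMOR) for i in range(50)]
    f = labeled_field(cells, tumor_mm2=0.5, stroma_mm2=0.5)
    rec = compartment_density(make_sample([f]), "CD8", TUMOR)
    assert rec.value == pytest.approx(100.0)
    assert rec.n_fields_used == 1


def test_density_is_unweighted_field_mean():
    f1 = labeled_field(
        [cell_with(f"a{i}", ("CD8",), TUMOR) for i in range(10)],
        tumor_mm2=0.1, stroma_mm2=0.1,
    )  # 100 / mm²
    f2 = labeled_field(
        [cell_with(f"b{i}", ("CD8",), TUMOR) for i in range(20)],
        tumor_mm2=0.1, stroma_mm2=0.1,
    )  # 200 / mm²
    f2.field_id = "F2"
    rec = compartment_density(make_sample([f1, f2]), "CD8", TUMOR)
    assert rec.value == pytest.approx(150.0)


def test_density_total_uses_pooled_counts_over_pooled_areas():
    # 10 tumor cells in 0.1 mm², 0 stromal cells in 0.3 mm²
    f = labeled_field(
        [cell_with(f"c{i}", ("CD8",), TUMOR) for i in range(10)],
        tumor_mm2=0.1, stroma_mm2=0.3,
    )
    rec = compartment_density(make_sample([f]), "CD8", "total")
    # pooled: 10 / 0.4 = 25, not mean(100, 0) = 50
    assert rec.value == pytest.approx(25.0)


def test_zero_area_fields_are_excluded_not_zeroed():
    f1 = labeled_field([cell_with("a", ("CD8",), STROMA)], tumor_mm2=0.0, stroma_mm2=0.2)
    sample = make_sample([f1])
    rec = compartment_density(sample, "CD8", TUMOR)
    assert rec.missing
    assert rec.n_fields_used == 0
    assert rec.n_fields_excluded == 1


def test_percentage_examples():
    cells = [cell_with(f"g{i}", ("CD8", "GranzymeB"), TUMOR) for i in range(5)]
    cells += [cell_with(f"p{i}", ("CD8",), TUMOR) for i in range(15)]
    f = labeled_field(cells)
    rec = phenotype_percentage(make_sample([f]), "CD8_GrzB", "CD8", TUMOR)
    assert rec.value == pytest.approx(25.0)  # 5 of 20 CD8+ are GrzB+

    f0 = labeled_field([cell_with(f"p{i}", ("CD8",), TUMOR) for i in range(20)])
    assert phenotype_percentage(make_sample([f0]), "CD8_GrzB", "CD8", TUMOR).value == 0.0


def test_percentage_is_field_mean_and_excludes_parentless_fields():
    fa = labeled_field(
        [cell_with("a1", ("CD8", "GranzymeB"), TUMOR)]
        + [cell_with(f"a{i}", ("CD8",), TUMOR) for i in range(2, 5)]
    )  # 25%
    fb = labeled_field(
        [cell_with(f"b{i}", ("CD8", "GranzymeB"), TUMOR) for i in range(3)]
        + [cell_with("b9", ("CD8",), TUMOR)]
    )  # 75%
    fb.field_id = "F2"
    fc = labeled_field([cell_with("c1", ("CD4",), TUMOR)])  # no CD8 parent
    fc.field_id = "F3"
    rec = phenotype_percentage(make_sample([fa, fb, fc]), "CD8_GrzB", "CD8", TUMOR)
    assert rec.value == pytest.approx(50.0)
    assert rec.n_fields_used == 2
    assert rec.n_fields_excluded == 1


def test_percentage_of_phenotype_among_itself_is_100():
    f = labeled_field([cell_with(f"c{i}", ("CD8",), TUMOR) for i in range(7)])
    rec = phenotype_percentage(make_sample([f]), "CD8", "CD8", TUMOR)
    assert rec.value == 100.0


def test_patient_aggregate_examples():
    assert patient_aggregate([1, 2, 3]) == (2.0, 3, 0)
    value, n_used, n_excl = patient_aggregate([])
    assert math.isnan(value) and n_used == 0
    assert patient_aggregate([10, None, 30]) == (20.0, 2, 1)
    assert patient_aggregate([10, 20, 30], excluded=[False, True, False]) == (20.0, 2, 1)


def test_density_additivity_and_compartment_partition(rng):
    # disjoint archetypes: density(CD4-only) + density(Treg) adds within a field,
    # and tumor + stroma counts equal the total count for every label
    cells = []
    for i in range(400):
        kind = rng.integers(0, 3)
        positive = [("CD4",), ("CD4", "FoxP3"), ("CD8",)][kind]
        comp = TUMOR if rng.random() < 0.4 else STROMA
        cells.append(cell_with(f"c{i}", positive, comp))
    f = labeled_field(cells, tumor_mm2=0.25, stroma_mm2=0.5)
    sample = make_sample([f])

    d_cd4 = compartment_density(sample, "CD4", TUMOR).value
    d_treg = compartment_density(sample, "Treg", TUMOR).value
    n_cd4_only = sum(
        1 for c in f.cells if c.compartment == TUMOR and c.phenotypes == frozenset({"CD4"})
    )
    assert d_cd4 - d_treg == pytest.approx(n_cd4_only / 0.25)

    for label in ("CD4", "Treg", "CD8"):
        t = compartment_density(sample, label, TUMOR).value * 0.25
        s = compartment_density(sample, label, STROMA).value * 0.5
        tot = compartment_density(sample, label, "total").value * 0.75
        assert t + s == pytest.approx(tot)
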