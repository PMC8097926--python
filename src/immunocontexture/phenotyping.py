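"""Phenotype assignment and compartment-specific density / percentage metrics.

Phenotype labels are derived from marker combinations (multi-label: a
CD8+ Granzyme B+ cell carries both ``CD8`` and ``CD8_GrzB``). Cells positive
for the melanoma-cocktail pseudo-marker outline the tumor and are labeled
``tumor`` only — they never receive immune labels, so double-positives are
treated as tumor cells.

Densities (cells/mm²) and percentage metrics are computed per field and
aggregated per patient as the unweighted mean over the usable fields, the
standard per-slide convention for 20X field acquisitions. Field exclusion is
metric-specific: a field with no tumor region is excluded from intra-tumoral
densities but still contributes stromal metrics, and a field with no parent
cells is excluded from the corresponding percentage. A patient with no
usable field gets an explicitly missing value (NaN, flagged), never a
silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io import STROMA, TUMOR, CellRecord, FieldTable, SampleSet
from .panels import PanelDefinition, TUMOR_LABEL, phenotype_panel

__all__ = [
    "DensityRecord",
    "assign_phenotypes",
    "field_counts",
    "compartment_density",
    "phenotype_percentage",
    "patient_aggregate",
]

TOTAL = "total"
ALL_IMMUNE = "__immune__"  # pseudo-parent: all phenotyped immune cells


@dataclass
class DensityRecord:
    """One phenotype × compartment × patient metric value."""

    patient_id: str
    phenotype: str
    compartment: str  # tumor | stroma | total
    value: float  # cells/mm² or %, NaN when missing
    metric: str  # density | percentage
    n_fields_used: int
    n_fields_excluded: int
    parent: str | None = None  # percentage denominators only

    @property
    def missing(self) -> bool:
        return math.isnan(self.value)


def assign_phenotypes(field: FieldTable, panel: PanelDefinition) -> FieldTable:
    """Return a copy of the field with phenotype labels filled in.

    Each cell receives every rule it satisfies; melanoma-cocktail-positive
    cells get the ``tumor`` label and nothing else.
    """
    if field.panel_id and field.panel_id != panel.panel_id:
        raise ValidationError(
            f"field {field.field_id} is {field.panel_id!r}, panel is {panel.panel_id!r}"
        )
    if field.cells:
        present = set(field.cells[0].markers)
        for rule in panel.rules:
            missing = (rule.required_positive | rule.required_negative) - present
            if missing:
                raise ValidationError(
                    f"rule {rule.name!r} references marker(s) {sorted(missing)} "
                    f"absent from field {field.field_id}"
                )
        if panel.tumor_marker not in present:
            raise ValidationError(
                f"tumor marker {panel.tumor_marker!r} absent from field {field.field_id}"
            )
    new_cells: list[CellRecord] = []
    for cell in field.cells:
        if cell.markers.get(panel.tumor_marker, False):
            labels = frozenset({TUMOR_LABEL})
        else:
            labels = frozenset(r.name for r in panel.rules if r.matches(cell.markers))
        new_cells.append(replace(cell, phenotypes=labels))
    return replace(field, cells=new_cells)


def field_counts(field: FieldTable) -> dict[tuple[str, str], int]:
    """Per-field phenotype × compartment counts, cached on the field object.

    The pseudo-phenotype ``__immune__`` counts cells carrying at least one
    non-tumor label, used as the default percentage denominator.
    """
    cached = getattr(field, "_count_cache", None)
    if cached is not None:
        return cached
    counts: dict[tuple[str, str], int] = {}
    for cell in field.cells:
        comp = cell.compartment
        for label in cell.phenotypes:
            key = (label, comp)
            counts[key] = counts.get(key, 0) + 1
        if cell.phenotypes and cell.phenotypes != frozenset({TUMOR_LABEL}):
            key = (ALL_IMMUNE, comp)
            counts[key] = counts.get(key, 0) + 1
    object.__setattr__(field, "_count_cache", counts)
    return counts


def _count(field: FieldTable, phenotype: str, compartment: str) -> int:
    counts = field_counts(field)
    if compartment == TOTAL:
        return counts.get((phenotype, TUMOR), 0) + counts.get((phenotype, STROMA), 0)
    return counts.get((phenotype, compartment), 0)


def _cell_has(cell: CellRecord, label: str) -> bool:
    if label == ALL_IMMUNE:
        return bool(cell.phenotypes) and cell.phenotypes != frozenset({TUMOR_LABEL})
    return label in cell.phenotypes


def _joint_count(field: FieldTable, child: str, parent: str, compartment: str) -> int:
    """Cells carrying both labels in the compartment (cached per pair)."""
    cache = getattr(field, "_pair_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(field, "_pair_cache", cache)
    key = (child, parent)
    if key not in cache:
        pair: dict[str, int] = {TUMOR: 0, STROMA: 0}
        for cell in field.cells:
            if _cell_has(cell, child) and _cell_has(cell, parent):
                pair[cell.compartment] += 1
        cache[key] = pair
    pair = cache[key]
    if compartment == TOTAL:
        return pair[TUMOR] + pair[STROMA]
    return pair[compartment]


def _field_area(field: FieldTable, compartment: str) -> float:
    if compartment == TOTAL:
        return field.compartment_areas[TUMOR] + field.compartment_areas[STROMA]
    return field.compartment_areas[compartment]


def patient_aggregate(
    values: Sequence[float | None], excluded: Sequence[bool] | None = None
) -> tuple[float, int, int]:
    """Unweighted mean over usable per-field values.

    ``None``/NaN entries (or entries flagged in ``excluded``) are dropped and
    counted; with no usable value the mean is NaN (missing is encoded, not
    thrown).
    """
    usable: list[float] = []
    n_excluded = 0
    for i, v in enumerate(values):
        if excluded is not None and excluded[i]:
            n_excluded += 1
            continue
        if v is None or (isinstance(v, float) and math.isnan(v)):
            n_excluded += 1
            continue
        usable.append(float(v))
    if not usable:
        return float("nan"), 0, n_excluded
    return float(np.mean(usable)), len(usable), n_excluded


def compartment_density(
    sample: SampleSet,
    phenotype: str,
    compartment: str,
    panel_id: str | None = None,
) -> DensityRecord:
    """Per-patient density of a phenotype in a compartment (cells/mm²).

    Per-field density is count ÷ compartment area; the ``total`` compartment
    uses (tumor + stroma counts) ÷ (tumor + stroma areas) per field — not the
    mean of the two compartment densities. The patient value is the
    unweighted mean over fields with positive area; zero-area fields are
    excluded and tallied.
    """
    if compartment not in (TUMOR, STROMA, TOTAL):
        raise ValidationError(f"unknown compartment {compartment!r}")
    if panel_id is None:
        panel_id = phenotype_panel(phenotype)
    fields = sample.fields_for_panel(panel_id)
    per_field: list[float | None] = []
    for f in fields:
        area = _field_area(f, compartment)
        if area <= 0:
            per_field.append(None)
            continue
        per_field.append(_count(f, phenotype, compartment) / area)
    value, n_used, n_excl = patient_aggregate(per_field)
    return DensityRecord(
        sample.patient_id, phenotype, compartment, value, "density", n_used, n_excl
    )


def phenotype_percentage(
    sample: SampleSet,
    phenotype: str,
    parent_phenotype: str | None,
    compartment: str,
    panel_id: str | None = None,
) -> DensityRecord:
    """Per-patient percentage of a phenotype among a parent population.

    Per-field percentage is 100 · count(phenotype ∧ parent) / count(parent);
    for the usual refinements (e.g. ``CD8_GrzB`` ⊂ ``CD8``) the joint count
    equals the phenotype count, but the joint is computed explicitly so that
    non-nested pairs behave. ``parent_phenotype=None`` uses all phenotyped immune
    cells of the panel in the compartment as the denominator. Fields with
    zero parent count are excluded; the patient value is the mean over the
    remaining fields.
    """
    if compartment not in (TUMOR, STROMA, TOTAL):
        raise ValidationError(f"unknown compartment {compartment!r}")
    parent_key = parent_phenotype if parent_phenotype is not None else ALL_IMMUNE
    if panel_id is None:
        panel_id = phenotype_panel(phenotype)
    fields = sample.fields_for_panel(panel_id)
    per_field: list[float | None] = []
    for f in fields:
        n_parent = _count(f, parent_key, compartment)
        if n_parent == 0:
            per_field.append(None)
            continue
        n_joint = _joint_count(f, phenotype, parent_key, compartment)
        per_field.append(100.0 * n_joint / n_parent)
    value, n_used, n_excl = patient_aggregate(per_field)
    return DensityRecord(
        sample.patient_id,
        phenotype,
        compartment,
        value,
        "percentage",
        n_used,
        n_excl,
        parent=parent_phenotype or "all_immune",
    )
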