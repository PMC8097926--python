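"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from immunocontexture.io import STROMA, TUMOR, CellRecord, FieldTable, SampleSet


def make_cell(
    cell_id: str,
    x: float,
    y: float,
    compartment: str = STROMA,
    markers: dict | None = None,
    phenotypes: frozenset | set = frozenset(),
) -> CellRecord:
    return CellRecord(cell_id, x, y, compartment, markers or {}, frozenset(phenotypes))


def make_field(
    cells,
    field_id: str = "F1",
    sample_id: str = "S1",
    panel_id: str = "panel2",
    tumor_mm2: float = 0.1,
    stroma_mm2: float = 0.2,
) -> FieldTable:
    return FieldTable(
        field_id,
        sample_id,
        panel_id,
        list(cells),
        {TUMOR: tumor_mm2, STROMA: stroma_mm2},
    )


def make_sample(fields, patient_id: str = "P1") -> SampleSet:
    return SampleSet(fields[0].sample_id, patient_id, "liver", list(fields))


def random_phenotype_field(rng: np.random.Generator, n_max: int = 500) -> FieldTable:
    """A random field with overlapping 'A'/'B' phenotype labels for oracle checks."""
    n = int(rng.integers(1, n_max + 1))
    cells = []
    for i in range(n):
        labels = set()
        if rng.random() < 0.5:
            labels.add("A")
        if rng.random() < 0.5:
            labels.add("B")
        cells.append(
            make_cell(
                f"c{i}",
                float(rng.uniform(0, 600)),
                float(rng.uniform(0, 450)),
                TUMOR if rng.random() < 0.3 else STROMA,
                phenotypes=frozenset(labels),
            )
        )
    return make_field(cells)


# ---------------------------------------------------------------------------
# O(n·m) brute-force oracles, kept deliberately naive and independent of the
# KD-tree implementation under test.


def _points(field: FieldTable, phenotype: str):
    pts = [(c.x_um, c.y_um) for c in field.cells if phenotype in c.phenotypes]
    ids = [c.cell_id for c in field.cells if phenotype in c.phenotypes]
    return np.asarray(pts, dtype=float).reshape(-1, 2), ids


def brute_nn_mean(field: FieldTable, reference: str, target: str) -> float | None:
    ref_pts, ref_ids = _points(field, reference)
    tgt_pts, tgt_ids = _points(field, target)
    if len(ref_ids) == 0 or len(tgt_ids) == 0:
        return None
    nearest = []
    for i in range(len(ref_ids)):
        best = math.inf
        for j in range(len(tgt_ids)):
            if ref_ids[i] == tgt_ids[j]:
                continue
            dx = ref_pts[i, 0] - tgt_pts[j, 0]
            dy = ref_pts[i, 1] - tgt_pts[j, 1]
            d = math.sqrt(dx * dx + dy * dy)
            if d < best:
                best = d
        if math.isfinite(best):
            nearest.append(best)
    if not nearest:
        return None
    return float(np.mean(np.asarray(nearest)))


def brute_fraction_within(
    field: FieldTable, reference: str, target: str, radius: float
) -> float | None:
    ref_pts, ref_ids = _points(field, reference)
    if len(ref_ids) == 0:
        return None
    tgt_pts, tgt_ids = _points(field, target)
    n_hit = 0
    for i in range(len(ref_ids)):
        for j in range(len(tgt_ids)):
            if ref_ids[i] == tgt_ids[j]:
                continue
            dx = ref_pts[i, 0] - tgt_pts[j, 0]
            dy = ref_pts[i, 1] - tgt_pts[j, 1]
            if math.sqrt(dx * dx + dy * dy) <= radius:
                n_hit += 1
                break
    return 100.0 * n_hit / len(ref_ids)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
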