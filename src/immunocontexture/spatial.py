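"""Cell-to-cell proximity metrics: nearest-neighbor distance and
fraction-within-radius.

Two phenoptr-style statistics are computed per field and averaged per
patient:

* **nearest-neighbor mean distance** — for every reference cell, the 2-D
  Euclidean center-to-center distance to the nearest target-phenotype cell
  in the same field, averaged over reference cells (µm);
* **fraction within radius** — the percentage of reference cells with at
  least one target-phenotype cell at distance <= radius. A distance exactly
  equal to the radius counts as within. Target absence is a valid 0%, not an
  exclusion; a field with no reference cells is excluded and tallied.

A cell is never its own neighbor: when the reference and target phenotypes
overlap, self-pairs are excluded by cell identity. Distances never cross
field borders (fields are acquired without overlaps, so cross-field
distances are undefined), and no edge-effect correction is applied — a
known bias near field borders shared with the upstream convention.

Neighbor queries use a scipy cKDTree; the package's contract is exact
floating-point agreement with a brute-force O(n·m) scan, which the test
suite enforces on randomized fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .io import FieldTable, SampleSet
from .phenotyping import patient_aggregate

__all__ = [
    "ProximityMetricSpec",
    "ProximityResult",
    "nearest_neighbor_mean_distance",
    "fraction_within_radius",
    "aggregate_spatial_metric",
    "PRESET_RADII_UM",
]

# 25-30 µm between cell centres indicates an enhanced probability of
# cell-to-cell contact given lymphocyte/melanoma cell dimensions.
PRESET_RADII_UM = (20.0, 25.0, 30.0)

NN_MEAN_DISTANCE = "nn_mean_distance"
FRACTION_WITHIN = "fraction_within"


@dataclass(frozen=True)
class ProximityMetricSpec:
    """A (metric, reference, target, radius) proximity analysis request."""

    metric: str  # nn_mean_distance | fraction_within
    reference: str
    target: str
    radius_um: float | None = None
    panel_id: str | None = None

    def __post_init__(self) -> None:
        if self.metric not in (NN_MEAN_DISTANCE, FRACTION_WITHIN):
            raise ValidationError(f"unknown proximity metric {self.metric!r}")
        if self.metric == FRACTION_WITHIN and (
            self.radius_um is None or self.radius_um <= 0
        ):
            raise ValidationError("fraction_within requires a positive radius")

    @property
    def name(self) -> str:
        if self.metric == NN_MEAN_DISTANCE:
            return f"nn|{self.reference}|{self.target}"
        return f"fwr|{self.reference}|{self.target}|{self.radius_um:g}"


@dataclass
class ProximityResult:
    metric: str
    reference: str
    target: str
    radius_um: float | None
    patient_id: str
    patient_value: float  # NaN when all fields excluded
    per_field_values: list[float | None]
    n_reference_cells: int
    n_fields_used: int
    n_fields_excluded: int

    @property
    def missing(self) -> bool:
        return math.isnan(self.patient_value)


def _phenotype_points(
    field: FieldTable, phenotype: str
) -> tuple[np.ndarray, list[str]]:
    pts = []
    ids = []
    for c in field.cells:
        if phenotype in c.phenotypes:
            pts.append((c.x_um, c.y_um))
            ids.append(c.cell_id)
    if not pts:
        return np.empty((0, 2)), ids
    return np.asarray(pts, dtype=float), ids


def nearest_neighbor_mean_distance(
    field: FieldTable, reference: str, target: str
) -> float | None:
    """Mean over reference cells of the distance to the nearest target cell.

    Returns None (field excluded for this metric) when there is no reference
    cell, or no admissible target after self-exclusion.
    """
    ref_pts, ref_ids = _phenotype_points(field, reference)
    tgt_pts, tgt_ids = _phenotype_points(field, target)
    if ref_pts.shape[0] == 0 or tgt_pts.shape[0] == 0:
        return None
    tgt_index = {cid: i for i, cid in enumerate(tgt_ids)}
    overlap = any(cid in tgt_index for cid in ref_ids)
    tree = cKDTree(tgt_pts)
    k = 2 if (overlap and tgt_pts.shape[0] >= 2) else 1
    if overlap and tgt_pts.shape[0] == 1:
        # the only target may be the reference cell itself
        dists = []
        for i, cid in enumerate(ref_ids):
            if cid in tgt_index:
                continue
            d, _ = tree.query(ref_pts[i])
            dists.append(float(d))
        if not dists:
            return None
        return float(np.mean(np.asarray(dists)))
    d, idx = tree.query(ref_pts, k=k)
    if k == 1:
        nearest = np.atleast_1d(d).astype(float)
    else:
        nearest = np.empty(ref_pts.shape[0])
        for i, cid in enumerate(ref_ids):
            self_idx = tgt_index.get(cid, -1)
            if idx[i, 0] == self_idx:
                nearest[i] = d[i, 1]
            else:
                nearest[i] = d[i, 0]
    return float(np.mean(nearest))


def fraction_within_radius(
    field: FieldTable, reference: str, target: str, radius_um: float
) -> float | None:
    """Percentage of reference cells with >= 1 target cell within the radius
    (boundary inclusive). None when the field has no reference cells."""
    if radius_um <= 0:
        raise ValidationError("radius must be positive")
    ref_pts, ref_ids = _phenotype_points(field, reference)
    if ref_pts.shape[0] == 0:
        return None
    tgt_pts, tgt_ids = _phenotype_points(field, target)
    if tgt_pts.shape[0] == 0:
        return 0.0
    tgt_index = {cid: i for i, cid in enumerate(tgt_ids)}
    tree = cKDTree(tgt_pts)
    neighborhoods = tree.query_ball_point(ref_pts, r=radius_um)
    n_hit = 0
    for i, cid in enumerate(ref_ids):
        hits = neighborhoods[i]
        self_idx = tgt_index.get(cid, -1)
        if self_idx >= 0:
            hits = [h for h in hits if h != self_idx]
        if hits:
            n_hit += 1
    return 100.0 * n_hit / ref_pts.shape[0]


def aggregate_spatial_metric(
    sample: SampleSet, spec: ProximityMetricSpec
) -> ProximityResult:
    """Apply a proximity spec to every field of a sample and average.

    The patient value is the unweighted mean over non-excluded fields;
    exclusions are tallied. With all fields excluded the value is NaN,
    flagged via ``missing``.
    """
    fields = sample.fields_for_panel(spec.panel_id)
    per_field: list[float | None] = []
    n_ref = 0
    for f in fields:
        n_ref += sum(1 for c in f.cells if spec.reference in c.phenotypes)
        if spec.metric == NN_MEAN_DISTANCE:
            per_field.append(nearest_neighbor_mean_distance(f, spec.reference, spec.target))
        else:
            per_field.append(
                fraction_within_radius(f, spec.reference, spec.target, spec.radius_um)
            )
    value, n_used, n_excl = patient_aggregate(per_field)
    return ProximityResult(
        metric=spec.metric,
        reference=spec.reference,
        target=spec.target,
        radius_um=spec.radius_um,
        patient_id=sample.patient_id,
        patient_value=value,
        per_field_values=per_field,
        n_reference_cells=n_ref,
        n_fields_used=n_used,
        n_fields_excluded=n_excl,
    )
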