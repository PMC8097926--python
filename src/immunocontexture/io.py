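"""Per-cell segmentation table I/O and sample assembly.

The on-disk format is a plain CSV/TSV with one row per segmented cell
(id, x/y position, tissue category, one 0/1 column per marker), optionally
preceded by ``#``-comment metadata lines carrying field identity and the two
compartment areas. inForm-style exports (``Cell X Position`` etc.) are read
through a :class:`ColumnMapping`.

Coordinates are continuous 2-D positions in micrometres, origin at the field
top-left, y increasing downward (image convention). Fields are analyzed
independently; there is no stitching into slide coordinates, so cross-field
distances are undefined by design.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

TUMOR = "tumor"
STROMA = "stroma"
COMPARTMENTS = (TUMOR, STROMA)

_TRUE_TOKENS = {"1", "true", "t", "yes", "y", "pos", "positive", "+"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n", "neg", "negative", "-", ""}

# decimal-point floats only; comma-decimal input must be rejected, not misread
_FLOAT_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")


def _parse_float(token: str, what: str, row: int) -> float:
    token = token.strip()
    if not _FLOAT_RE.match(token):
        raise SchemaError(f"row {row}: cannot parse {what} value {token!r} as a number")
    return float(token)


def _parse_bool(token: str, what: str, row: int) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise SchemaError(f"row {row}: cannot parse {what} value {token!r} as positivity")


@dataclass
class CellRecord:
    """One segmented cell: position (µm), compartment, marker map, phenotype labels."""

    cell_id: str
    x_um: float
    y_um: float
    compartment: str
    markers: dict[str, bool] = field(default_factory=dict)
    phenotypes: frozenset[str] = frozenset()

    def validate(self) -> None:
        if not (math.isfinite(self.x_um) and math.isfinite(self.y_um)):
            raise ValidationError(f"cell {self.cell_id}: non-finite coordinates")
        if self.x_um < 0 or self.y_um < 0:
            raise ValidationError(f"cell {self.cell_id}: negative coordinates")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"cell {self.cell_id}: compartment {self.compartment!r} not in {COMPARTMENTS}"
            )


@dataclass
class FieldTable:
    """All cells of one imaged field plus the field's compartment areas (mm²)."""

    field_id: str
    sample_id: str
    panel_id: str
    cells: list[CellRecord]
    compartment_areas: dict[str, float]
    scale_um_per_px: float = 1.0

    def validate(self) -> None:
        areas = self.compartment_areas
        missing = [c for c in COMPARTMENTS if c not in areas]
        if missing:
            raise ValidationError(f"field {self.field_id}: missing areas for {missing}")
        if any(areas[c] < 0 for c in COMPARTMENTS):
            raise ValidationError(f"field {self.field_id}: negative compartment area")
        if not any(areas[c] > 0 for c in COMPARTMENTS):
            raise ValidationError(f"field {self.field_id}: all compartment areas are zero")
        seen: set[str] = set()
        for cell in self.cells:
            cell.validate()
            if cell.cell_id in seen:
                raise ValidationError(
                    f"field {self.field_id}: duplicate cell_id {cell.cell_id!r}"
                )
            seen.add(cell.cell_id)
            if areas[cell.compartment] <= 0:
                raise ValidationError(
                    f"field {self.field_id}: cell {cell.cell_id} lies in "
                    f"{cell.compartment!r} which has zero area"
                )

    @property
    def marker_names(self) -> tuple[str, ...]:
        if not self.cells:
            return ()
        return tuple(self.cells[0].markers.keys())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row: dict[str, object] = {
                "cell_id": c.cell_id,
                "x_um": c.x_um,
                "y_um": c.y_um,
                "tissue_category": c.compartment,
            }
            for m, v in c.markers.items():
                row[m] = int(v)
            row["phenotypes"] = ";".join(sorted(c.phenotypes))
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ClinicalRecord:
    """Per-patient clinical metadata and outcome."""

    patient_id: str
    metastasis_site: str = "liver"  # liver | extra_hepatic
    recist: str | None = None  # CR | PR | SD | PD
    os_months: float | None = None
    event: bool | None = None  # death observed
    treatment_class: str | None = None  # immunotherapy | other
    tls_present: bool | None = None


@dataclass
class SampleSet:
    """All fields of one patient sample (possibly spanning both panels)."""

    sample_id: str
    patient_id: str
    metastasis_site: str
    fields: list[FieldTable]
    clinical: ClinicalRecord | None = None

    def validate(self) -> None:
        if not self.fields:
            raise ValidationError(f"sample {self.sample_id}: no fields")
        bad = {f.sample_id for f in self.fields} - {self.sample_id}
        if bad:
            raise ValidationError(
                f"sample {self.sample_id}: fields carry foreign sample ids {sorted(bad)}"
            )

    def fields_for_panel(self, panel_id: str | None) -> list[FieldTable]:
        if panel_id is None:
            return list(self.fields)
        return [f for f in self.fields if f.panel_id == panel_id]


@dataclass(frozen=True)
class ColumnMapping:
    """Maps logical columns to source headers, with the coordinate unit."""

    cell_id: str = "cell_id"
    x: str = "x_um"
    y: str = "y_um"
    tissue_category: str = "tissue_category"
    markers: Mapping[str, str] = None  # logical marker name -> source header
    coordinate_unit: str = "um"  # um | pixel

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValidationError("ColumnMapping: marker set must be non-empty")
        if self.coordinate_unit not in ("um", "pixel"):
            raise ValidationError(
                f"ColumnMapping: unknown coordinate unit {self.coordinate_unit!r}"
            )

    @classmethod
    def native(cls, markers: Sequence[str]) -> "ColumnMapping":
        """Mapping for tables written by :func:`write_cell_table`."""
        return cls(markers={m: m for m in markers})

    @classmethod
    def inform(cls, markers: Mapping[str, str]) -> "ColumnMapping":
        """Mapping for inForm-style cell seg exports (pixel coordinates)."""
        return cls(
            cell_id="Cell ID",
            x="Cell X Position",
            y="Cell Y Position",
            tissue_category="Tissue Category",
            markers=dict(markers),
            coordinate_unit="pixel",
        )


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def read_cell_table(
    path: str | Path,
    mapping: ColumnMapping | None = None,
    scale_um_per_px: float = 1.0,
    *,
    sep: str = ",",
    field_id: str | None = None,
    sample_id: str | None = None,
    panel_id: str | None = None,
    compartment_areas: Mapping[str, float] | None = None,
) -> FieldTable:
    """Read one per-cell segmentation table into a validated :class:`FieldTable`.

    Pixel coordinates are converted to µm via ``scale_um_per_px``. Field
    identity and compartment areas come from keyword arguments or, if absent,
    from ``#``-comment metadata lines in the file itself.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cell table not found: {path}")
    meta = _read_metadata(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)

    marker_map: Mapping[str, str]
    if mapping is None:
        marker_cols = [
            c
            for c in df.columns
            if c not in ("cell_id", "x_um", "y_um", "tissue_category", "phenotypes")
        ]
        # a cell-free field legitimately has no marker columns on disk
        marker_map = {m: m for m in marker_cols}
        mapping = ColumnMapping.native(marker_cols) if marker_cols else None
        id_col, x_col, y_col, cat_col = "cell_id", "x_um", "y_um", "tissue_category"
        unit = "um"
    else:
        marker_map = dict(mapping.markers)
        id_col, x_col, y_col, cat_col = (
            mapping.cell_id,
            mapping.x,
            mapping.y,
            mapping.tissue_category,
        )
        unit = mapping.coordinate_unit

    needed = [id_col, x_col, y_col, cat_col]
    needed += list(marker_map.values())
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mapped column(s) {missing}")

    unit_scale = scale_um_per_px if unit == "pixel" else 1.0

    cells: list[CellRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowmap = dict(zip(df.columns, row))
        x = _parse_float(rowmap[x_col], "x coordinate", i) * unit_scale
        y = _parse_float(rowmap[y_col], "y coordinate", i) * unit_scale
        cat = rowmap[cat_col].strip().lower()
        if cat not in COMPARTMENTS:
            raise SchemaError(
                f"row {i}: unknown tissue category {rowmap[cat_col]!r}; "
                f"allowed values: {list(COMPARTMENTS)}"
            )
        markers = {
            name: _parse_bool(rowmap[src], f"marker {name}", i)
            for name, src in marker_map.items()
        }
        phen_raw = rowmap.get("phenotypes", "")
        phenotypes = frozenset(p for p in phen_raw.split(";") if p)
        cells.append(CellRecord(str(rowmap[id_col]), x, y, cat, markers, phenotypes))

    areas: dict[str, float] = {}
    if compartment_areas is not None:
        areas = {c: float(compartment_areas[c]) for c in COMPARTMENTS}
    elif "tumor_mm2" in meta and "stroma_mm2" in meta:
        areas = {TUMOR: float(meta["tumor_mm2"]), STROMA: float(meta["stroma_mm2"])}
    else:
        raise SchemaError(
            f"{path.name}: compartment areas not given and not present in file metadata"
        )

    table = FieldTable(
        field_id=field_id or meta.get("field_id", path.stem),
        sample_id=sample_id or meta.get("sample_id", ""),
        panel_id=panel_id or meta.get("panel_id", ""),
        cells=cells,
        compartment_areas=areas,
        scale_um_per_px=scale_um_per_px,
    )
    table.validate()
    return table


def write_cell_table(table: FieldTable, path: str | Path, *, sep: str = ",") -> None:
    """Write a field to CSV/TSV; ``read(write(f))`` reproduces cells to 6
    decimals in the coordinates and compartment areas exactly."""
    table.validate()
    path = Path(path)
    markers = table.marker_names
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# field_id={table.field_id}\n")
        fh.write(f"# sample_id={table.sample_id}\n")
        fh.write(f"# panel_id={table.panel_id}\n")
        fh.write(f"# tumor_mm2={table.compartment_areas[TUMOR]!r}\n")
        fh.write(f"# stroma_mm2={table.compartment_areas[STROMA]!r}\n")
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["cell_id", "x_um", "y_um", "tissue_category", *markers, "phenotypes"])
        for c in table.cells:
            writer.writerow(
                [
                    c.cell_id,
                    f"{c.x_um:.6f}",
                    f"{c.y_um:.6f}",
                    c.compartment,
                    *(int(c.markers.get(m, False)) for m in markers),
                    ";".join(sorted(c.phenotypes)),
                ]
            )


def assemble_sample(
    fields: Sequence[FieldTable], clinical: ClinicalRecord | None = None
) -> SampleSet:
    """Assemble the fields of one sample; panels stay distinct (consecutive
    sections are never merged cell-wise)."""
    if not fields:
        raise ValidationError("assemble_sample: zero fields")
    sample_ids = {f.sample_id for f in fields}
    if len(sample_ids) != 1:
        raise ValidationError(f"assemble_sample: mixed sample ids {sorted(sample_ids)}")
    sample_id = fields[0].sample_id
    site = clinical.metastasis_site if clinical else "liver"
    patient_id = clinical.patient_id if clinical else sample_id
    sample = SampleSet(sample_id, patient_id, site, list(fields), clinical)
    sample.validate()
    return sample


def read_area_sidecar(path: str | Path, *, sep: str = "\t") -> dict[str, dict[str, float]]:
    """Read a per-field area table (field_id, tumor_mm2, stroma_mm2)."""
    df = pd.read_csv(path, sep=sep)
    for col in ("field_id", "tumor_mm2", "stroma_mm2"):
        if col not in df.columns:
            raise SchemaError(f"area sidecar {path}: missing column {col!r}")
    return {
        str(r.field_id): {TUMOR: float(r.tumor_mm2), STROMA: float(r.stroma_mm2)}
        for r in df.itertuples(index=False)
    }


def read_clinical_table(path: str | Path, *, sep: str = "\t") -> dict[str, ClinicalRecord]:
    """Read the per-patient clinical table.

    Expected columns: patient_id, site, response, os_months, event,
    treatment_class, tls_present (the last three optional).
    """
    df = pd.read_csv(path, sep=sep)
    for col in ("patient_id", "site", "response", "os_months", "event"):
        if col not in df.columns:
            raise SchemaError(f"clinical table {path}: missing column {col!r}")
    out: dict[str, ClinicalRecord] = {}
    for r in df.itertuples(index=False):
        rec = ClinicalRecord(
            patient_id=str(r.patient_id),
            metastasis_site=str(r.site),
            recist=str(r.response),
            os_months=float(r.os_months),
            event=bool(int(r.event)),
            treatment_class=str(getattr(r, "treatment_class", "") or "") or None,
            tls_present=bool(int(getattr(r, "tls_present", 0)))
            if hasattr(r, "tls_present")
            else None,
        )
        out[rec.patient_id] = rec
    return out


def round_trip_equal(a: FieldTable, b: FieldTable, tol: float = 5e-7) -> bool:
    """True when two fields agree cell-by-cell within coordinate tolerance."""
    if len(a.cells) != len(b.cells) or a.compartment_areas != b.compartment_areas:
        return False
    for ca, cb in zip(a.cells, b.cells):
        if ca.cell_id != cb.cell_id or ca.compartment != cb.compartment:
            return False
        if abs(ca.x_um - cb.x_um) > tol or abs(ca.y_um - cb.y_um) > tol:
            return False
        if ca.markers != cb.markers or ca.phenotypes != cb.phenotypes:
            return False
    return True
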