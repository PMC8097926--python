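"""Marker panels and phenotype rules.

Two staining panels are modeled, mirroring a common two-panel design for
melanoma metastasis profiling:

* ``panel1`` — lineage panel: CD20 (B cells), CD3 (T cells), CD68
  (macrophages), CD56 (NK cells), NE (neutrophil elastase, neutrophils),
  plus a melanoma-cocktail pseudo-marker used to outline tumor cells.
* ``panel2`` — functional T-cell panel: CD4, CD8, Granzyme B, FoxP3, CD163
  (M2-polarized macrophages), plus the same melanoma pseudo-marker.

A :class:`PhenotypeRule` maps a marker-positivity combination to a phenotype
label; rules are multi-label (a CD8+ Granzyme B+ cell carries both ``CD8``
and ``CD8_GrzB``). Cells positive for the melanoma pseudo-marker are labeled
``tumor`` and receive no immune labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

TUMOR_LABEL = "tumor"
MELANOMA_MARKER = "melanoma"


@dataclass(frozen=True)
class PhenotypeRule:
    """A marker-combination rule defining one phenotype label."""

    name: str
    required_positive: frozenset[str]
    required_negative: frozenset[str] = frozenset()
    panel_id: str = "panel2"

    def __post_init__(self) -> None:
        if not self.required_positive:
            raise ValidationError(f"rule {self.name!r}: required_positive must be non-empty")
        if self.required_positive & self.required_negative:
            raise ValidationError(
                f"rule {self.name!r}: positive and negative marker sets overlap"
            )

    def matches(self, markers: dict[str, bool]) -> bool:
        return all(markers.get(m, False) for m in self.required_positive) and not any(
            markers.get(m, False) for m in self.required_negative
        )


@dataclass(frozen=True)
class PanelDefinition:
    """One staining panel: its marker list and ordered phenotype rules."""

    panel_id: str
    markers: tuple[str, ...]
    rules: tuple[PhenotypeRule, ...]
    tumor_marker: str = MELANOMA_MARKER

    def __post_init__(self) -> None:
        marker_set = set(self.markers)
        for rule in self.rules:
            extra = (rule.required_positive | rule.required_negative) - marker_set
            if extra:
                raise ValidationError(
                    f"rule {rule.name!r} references markers not in panel "
                    f"{self.panel_id!r}: {sorted(extra)}"
                )

    @property
    def phenotype_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.rules)


def _rule(name: str, pos: tuple[str, ...], panel: str) -> PhenotypeRule:
    return PhenotypeRule(name, frozenset(pos), frozenset(), panel)


PANEL1 = PanelDefinition(
    panel_id="panel1",
    markers=("CD20", "CD3", "CD68", "CD56", "NE", MELANOMA_MARKER),
    rules=(
        _rule("CD20", ("CD20",), "panel1"),
        _rule("CD3", ("CD3",), "panel1"),
        _rule("CD68", ("CD68",), "panel1"),
        _rule("CD56", ("CD56",), "panel1"),
        _rule("NE", ("NE",), "panel1"),
    ),
)

PANEL2 = PanelDefinition(
    panel_id="panel2",
    markers=("CD4", "CD8", "GranzymeB", "FoxP3", "CD163", MELANOMA_MARKER),
    rules=(
        _rule("CD4", ("CD4",), "panel2"),
        _rule("CD8", ("CD8",), "panel2"),
        _rule("Treg", ("CD4", "FoxP3"), "panel2"),
        _rule("CD8_GrzB", ("CD8", "GranzymeB"), "panel2"),
        _rule("CD4_GrzB", ("CD4", "GranzymeB"), "panel2"),
        _rule("CD163", ("CD163",), "panel2"),
    ),
)

DEFAULT_PANELS: dict[str, PanelDefinition] = {"panel1": PANEL1, "panel2": PANEL2}

# Cell archetypes used by the simulator: the marker set a simulated cell of a
# given kind is positive for. Archetypes are disjoint cell populations; a
# phenotype *label* may cover several archetypes (e.g. the "CD8" label counts
# both the CD8 and the CD8_GrzB archetype).
ARCHETYPE_MARKERS: dict[str, dict[str, frozenset[str]]] = {
    "panel1": {
        "CD20": frozenset({"CD20"}),
        "CD3": frozenset({"CD3"}),
        "CD68": frozenset({"CD68"}),
        "CD56": frozenset({"CD56"}),
        "NE": frozenset({"NE"}),
        TUMOR_LABEL: frozenset({MELANOMA_MARKER}),
    },
    "panel2": {
        "CD4": frozenset({"CD4"}),
        "CD8": frozenset({"CD8"}),
        "Treg": frozenset({"CD4", "FoxP3"}),
        "CD8_GrzB": frozenset({"CD8", "GranzymeB"}),
        "CD4_GrzB": frozenset({"CD4", "GranzymeB"}),
        "CD163": frozenset({"CD163"}),
        TUMOR_LABEL: frozenset({MELANOMA_MARKER}),
    },
}


def phenotype_panel(phenotype: str) -> str | None:
    """Return the panel a phenotype label belongs to, or None if ambiguous.

    ``tumor`` exists on both panels (the melanoma cocktail is in both stains),
    so it maps to None and callers must either pick a panel or use all fields.
    """
    if phenotype == TUMOR_LABEL:
        return None
    hits = [p.panel_id for p in DEFAULT_PANELS.values() if phenotype in p.phenotype_names]
    if len(hits) == 1:
        return hits[0]
    return None
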