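"""Synthetic multiplex-IHC tissue cohorts with known ground truth.

The simulator emulates the structure of an inForm-style study: each patient
contributes >= 20 imaged fields per staining panel, every field is split
into a tumor compartment (a union of disc-shaped tumor nests) and the
surrounding stroma, and each cell archetype is placed by a homogeneous
Poisson process with separate intra-tumoral and stromal intensities
(cells/mm²). An optional proximity layer re-places a configured fraction of
a target population uniformly within a given radius of randomly chosen
anchor cells, creating known spatial association. A proportional-hazards
survival layer links per-patient outcomes to configured covariates
(explicit per-patient features, true intensity features, or random binary
arms).

Geometry and areas
------------------
Tumor nests are discs with uniformly random centres (or explicit centres),
clipped at the field border; overlapping nests are unioned. The tumor mask
is rasterized at 1 µm resolution (pixel-centre rule) and cells are placed
uniformly over the same raster, so the realized density is an unbiased
estimator of the configured intensity with respect to the *recorded*
compartment area by construction.

Everything is reproducible: a single integer seed drives the cohort, and
per-field seeds are derived deterministically via ``SeedSequence`` spawn
keys so that individual fields can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io import STROMA, TUMOR, CellRecord, ClinicalRecord, FieldTable, SampleSet
from .panels import ARCHETYPE_MARKERS, TUMOR_LABEL
from .stats import SurvivalRecord

__all__ = [
    "ProximityPlacement",
    "SurvivalSpec",
    "SimulationConfig",
    "CohortGroundTruth",
    "simulate_field",
    "simulate_cohort",
    "write_ground_truth",
]

# intensity maps are nested: panel_id -> archetype -> (tumor λ, stroma λ) in cells/mm²
IntensityMap = Mapping[str, Mapping[str, tuple[float, float]]]

MM2_PER_UM2 = 1e-6


@dataclass(frozen=True)
class ProximityPlacement:
    """Re-place ``attracted_fraction`` of *target* cells within
    ``placement_radius_um`` of a random *anchor* cell (same field, same panel)."""

    target: str
    anchor: str
    attracted_fraction: float
    placement_radius_um: float
    panel_id: str = "panel2"

    def __post_init__(self) -> None:
        if not (0.0 <= self.attracted_fraction <= 1.0):
            raise ConfigError("attracted_fraction must lie in [0, 1]")
        if self.placement_radius_um <= 0:
            raise ConfigError("placement_radius_um must be positive")


@dataclass(frozen=True)
class SurvivalSpec:
    """Proportional-hazards outcome layer.

    ``baseline_hazard`` is the event rate per month for a patient with all
    covariates at zero. ``coefficients`` maps feature names to log-hazard
    coefficients; features are resolved per patient (see
    :func:`simulate_cohort`). A Bernoulli(``censoring_rate``) thinning
    censors selected patients at a uniform time before their event;
    ``horizon_months`` administratively censors beyond the follow-up window
    (None disables the cap).
    """

    baseline_hazard: float = 1.0 / 40.0
    coefficients: Mapping[str, float] = dc_field(default_factory=dict)
    censoring_rate: float = 0.0
    horizon_months: float | None = 171.0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline hazard must be positive")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ConfigError("censoring rate must lie in [0, 1)")
        if self.horizon_months is not None and self.horizon_months <= 0:
            raise ConfigError("follow-up horizon must be positive")


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort."""

    intensities: IntensityMap
    n_patients: int = 21
    n_fields_per_patient: int = 20
    field_width_um: float = 669.0
    field_height_um: float = 500.0
    tumor_nest_count: int = 3
    tumor_nest_radius_um: float = 120.0
    tumor_nest_centers: Sequence[tuple[float, float]] | None = None
    proximity_spec: Sequence[ProximityPlacement] = ()
    survival: SurvivalSpec = dc_field(default_factory=SurvivalSpec)
    patient_features: Mapping[str, Sequence[float]] | None = None
    response_counts: Mapping[str, int] | None = None
    response_profiles: Mapping[str, IntensityMap] | None = None  # keyed by DCR group
    site_liver_fraction: float = 17 / 21
    immunotherapy_fraction: float = 13 / 21
    tls_fraction: float = 6 / 21
    misclassification_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ConfigError("field dimensions must be positive")
        if self.n_fields_per_patient < 1:
            raise ConfigError("need at least one field per patient")
        if self.tumor_nest_count < 0 or self.tumor_nest_radius_um < 0:
            raise ConfigError("nest count and radius must be non-negative")
        if not (0.0 <= self.misclassification_rate <= 1.0):
            raise ConfigError("misclassification rate must lie in [0, 1]")
        for panel_id, arch_map in self.intensities.items():
            if panel_id not in ARCHETYPE_MARKERS:
                raise ConfigError(f"unknown panel {panel_id!r} in intensity map")
            for name, (lam_t, lam_s) in arch_map.items():
                if name not in ARCHETYPE_MARKERS[panel_id]:
                    raise ConfigError(
                        f"unknown archetype {name!r} for panel {panel_id!r}"
                    )
                if lam_t < 0 or lam_s < 0:
                    raise ConfigError(f"negative intensity for {panel_id}/{name}")
        for spec in self.proximity_spec:
            arch_map = self.intensities.get(spec.panel_id, {})
            for who in (spec.target, spec.anchor):
                if who not in arch_map:
                    raise ConfigError(
                        f"proximity spec references {who!r} absent from the "
                        f"{spec.panel_id} intensity map"
                    )
        # frozen dataclass __post_init__ already checked SurvivalSpec bounds
        if self.response_counts is not None:
            total = sum(self.response_counts.values())
            if total != self.n_patients:
                raise ConfigError(
                    f"response counts sum to {total}, expected {self.n_patients}"
                )
            unknown = set(self.response_counts) - {"CR", "PR", "SD", "PD"}
            if unknown:
                raise ConfigError(f"unknown RECIST codes {sorted(unknown)}")
        if self.patient_features is not None:
            for name, vals in self.patient_features.items():
                if len(vals) != self.n_patients:
                    raise ConfigError(
                        f"patient feature {name!r} has {len(vals)} values, "
                        f"expected {self.n_patients}"
                    )


@dataclass
class CohortGroundTruth:
    """Configured truth behind a simulated cohort."""

    patient_ids: list[str]
    # patient -> panel -> archetype -> (tumor λ, stroma λ)
    intensities: dict[str, dict[str, dict[str, tuple[float, float]]]]
    attracted_fractions: dict[tuple[str, str, str], float]  # (panel, target, anchor) -> f
    coefficients: dict[str, float]
    features: dict[str, dict[str, float]]  # feature -> patient -> value
    groups: dict[str, dict[str, object]]  # patient -> {recist, dcr_group, site, ...}

    def expected_density(
        self, patient_id: str, panel_id: str, archetype: str, compartment: str
    ) -> float:
        lam_t, lam_s = self.intensities[patient_id][panel_id][archetype]
        return lam_t if compartment == TUMOR else lam_s


def _tumor_mask(
    width_um: float,
    height_um: float,
    centers: Sequence[tuple[float, float]],
    radius_um: float,
) -> np.ndarray:
    """Boolean raster of the tumor compartment at 1 µm resolution."""
    w = max(int(round(width_um)), 1)
    h = max(int(round(height_um)), 1)
    mask = np.zeros((h, w), dtype=bool)
    if not centers or radius_um <= 0:
        return mask
    xs = np.arange(w, dtype=float) + 0.5
    ys = np.arange(h, dtype=float) + 0.5
    r2 = radius_um * radius_um
    for cx, cy in centers:
        dx2 = (xs - cx) ** 2
        dy2 = (ys - cy) ** 2
        mask |= dy2[:, None] + dx2[None, :] <= r2
    return mask


def _place_uniform(
    rng: np.random.Generator, flat_idx: np.ndarray, width: int, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n points uniformly over the region given by flat pixel indices."""
    pick = rng.integers(0, flat_idx.size, size=n)
    idx = flat_idx[pick]
    iy, ix = np.divmod(idx, width)
    x = ix + rng.random(n)
    y = iy + rng.random(n)
    return x, y


def simulate_field(
    config: SimulationConfig,
    patient_profile: IntensityMap | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    panel_id: str | None = None,
    field_id: str = "F1",
    sample_id: str = "S1",
) -> FieldTable:
    """Simulate one imaged field for one panel.

    ``patient_profile`` partially overrides the configured intensity map
    (per panel, per archetype). Fully reproducible for a fixed seed.
    """
    config.validate()
    intensities = _merged_intensities(config.intensities, patient_profile)
    if panel_id is None:
        if len(intensities) != 1:
            raise ConfigError(
                "panel_id must be given when the intensity map covers several panels"
            )
        panel_id = next(iter(intensities))
    if panel_id not in intensities:
        raise ConfigError(f"no intensities configured for panel {panel_id!r}")
    rng = np.random.default_rng(seed)

    if config.tumor_nest_centers is not None:
        centers = [tuple(c) for c in config.tumor_nest_centers]
    else:
        centers = [
            (
                rng.uniform(0, config.field_width_um),
                rng.uniform(0, config.field_height_um),
            )
            for _ in range(config.tumor_nest_count)
        ]
    mask = _tumor_mask(
        config.field_width_um, config.field_height_um, centers, config.tumor_nest_radius_um
    )
    h, w = mask.shape
    tumor_px = np.flatnonzero(mask.ravel())
    stroma_px = np.flatnonzero(~mask.ravel())
    area = {
        TUMOR: tumor_px.size * MM2_PER_UM2,
        STROMA: stroma_px.size * MM2_PER_UM2,
    }
    if area[TUMOR] + area[STROMA] <= 0:
        raise ConfigError("total compartment area is zero")

    arch_map = intensities[panel_id]
    pos_x: list[np.ndarray] = []
    pos_y: list[np.ndarray] = []
    arch_of: list[str] = []
    for name in sorted(arch_map):
        lam_t, lam_s = arch_map[name]
        for compartment, lam, px in (
            (TUMOR, lam_t, tumor_px),
            (STROMA, lam_s, stroma_px),
        ):
            if lam == 0:
                continue
            if area[compartment] <= 0:
                raise ConfigError(
                    f"archetype {name!r} has positive {compartment} intensity but "
                    f"the {compartment} compartment has zero area"
                )
            n = int(rng.poisson(lam * area[compartment]))
            if n == 0:
                continue
            x, y = _place_uniform(rng, px, w, n)
            pos_x.append(x)
            pos_y.append(y)
            arch_of.extend([name] * n)

    if pos_x:
        x_all = np.concatenate(pos_x)
        y_all = np.concatenate(pos_y)
    else:
        x_all = np.empty(0)
        y_all = np.empty(0)
    arch_arr = np.array(arch_of, dtype=object)

    # proximity layer: re-place a fraction of target cells near random anchors
    for spec in config.proximity_spec:
        if spec.panel_id != panel_id:
            continue
        anchor_idx = np.flatnonzero(arch_arr == spec.anchor)
        target_idx = np.flatnonzero(arch_arr == spec.target)
        if anchor_idx.size == 0 or target_idx.size == 0:
            continue
        chosen = target_idx[rng.random(target_idx.size) < spec.attracted_fraction]
        for ti in chosen:
            ai = anchor_idx[rng.integers(0, anchor_idx.size)]
            ax, ay = x_all[ai], y_all[ai]
            while True:  # rejection-sample uniform in the disc, inside the field
                r = spec.placement_radius_um * math.sqrt(rng.random())
                theta = rng.random() * 2.0 * math.pi
                nx, ny = ax + r * math.cos(theta), ay + r * math.sin(theta)
                if 0.0 <= nx < w and 0.0 <= ny < h:
                    break
            x_all[ti], y_all[ti] = nx, ny

    marker_names = _panel_marker_order(panel_id)
    cells: list[CellRecord] = []
    for i in range(x_all.size):
        x, y = float(x_all[i]), float(y_all[i])
        compartment = TUMOR if mask[min(int(y), h - 1), min(int(x), w - 1)] else STROMA
        positive = ARCHETYPE_MARKERS[panel_id][arch_arr[i]]
        markers = {m: (m in positive) for m in marker_names}
        if config.misclassification_rate > 0:
            flips = rng.random(len(marker_names)) < config.misclassification_rate
            markers = {
                m: (not v if f else v)
                for (m, v), f in zip(markers.items(), flips)
            }
        cells.append(CellRecord(f"c{i}", x, y, compartment, markers))

    table = FieldTable(field_id, sample_id, panel_id, cells, area)
    table.validate()
    return table


def _panel_marker_order(panel_id: str) -> tuple[str, ...]:
    seen: list[str] = []
    for ms in ARCHETYPE_MARKERS[panel_id].values():
        for m in sorted(ms):
            if m not in seen:
                seen.append(m)
    return tuple(sorted(seen))


def _merged_intensities(
    base: IntensityMap, override: IntensityMap | None
) -> dict[str, dict[str, tuple[float, float]]]:
    merged = {p: dict(m) for p, m in base.items()}
    if override:
        for panel_id, arch_map in override.items():
            merged.setdefault(panel_id, {}).update(arch_map)
    return merged


def _exact_split(
    rng: np.random.Generator, n: int, fraction: float, yes: object, no: object
) -> list[object]:
    n_yes = int(round(n * fraction))
    labels = [yes] * n_yes + [no] * (n - n_yes)
    rng.shuffle(labels)
    return labels


def _assign_responses(rng: np.random.Generator, config: SimulationConfig) -> list[str]:
    if config.response_counts is not None:
        labels: list[str] = []
        for code in ("PD", "SD", "PR", "CR"):
            labels += [code] * int(config.response_counts.get(code, 0))
        rng.shuffle(labels)
        return labels
    codes = np.array(["PD", "SD", "PR", "CR"])
    probs = np.array([7, 7, 6, 1], dtype=float) / 21.0
    return list(rng.choice(codes, size=config.n_patients, p=probs))


def _resolve_features(
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_intensities: list[dict[str, dict[str, tuple[float, float]]]],
) -> dict[str, np.ndarray]:
    """Resolve each survival coefficient's per-patient feature values.

    Resolution order: explicit ``patient_features`` entry; a
    ``density:<panel>:<archetype>:<compartment>`` name, z-scored across the
    cohort from the true intensities; otherwise an i.i.d. Bernoulli(0.5)
    binary arm.
    """
    n = config.n_patients
    out: dict[str, np.ndarray] = {}
    for name in config.survival.coefficients:
        if config.patient_features and name in config.patient_features:
            out[name] = np.asarray(config.patient_features[name], dtype=float)
        elif name.startswith("density:"):
            _, panel_id, archetype, compartment = name.split(":")
            idx = 0 if compartment == TUMOR else 1
            vals = np.array(
                [patient_intensities[i][panel_id][archetype][idx] for i in range(n)]
            )
            sd = vals.std()
            out[name] = (vals - vals.mean()) / sd if sd > 0 else np.zeros(n)
        else:
            out[name] = rng.integers(0, 2, size=n).astype(float)
    return out


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SampleSet], list[SurvivalRecord], CohortGroundTruth]:
    """Simulate a full cohort: tissue fields per panel, clinical groups and
    proportional-hazards survival outcomes, plus the ground truth."""
    config.validate()
    if config.n_patients < 2:
        raise ConfigError("need at least two patients")
    master = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))

    patient_ids = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    responses = _assign_responses(master, config)
    dcr = ["CD" if r in ("CR", "PR", "SD") else "PD" for r in responses]
    sites = _exact_split(master, config.n_patients, config.site_liver_fraction, "liver", "extra_hepatic")
    treatments = _exact_split(
        master, config.n_patients, config.immunotherapy_fraction, "immunotherapy", "other"
    )
    tls = _exact_split(master, config.n_patients, config.tls_fraction, True, False)

    # effective per-patient intensities (DCR-group profile overrides)
    patient_intensities: list[dict[str, dict[str, tuple[float, float]]]] = []
    for i in range(config.n_patients):
        profile = None
        if config.response_profiles:
            profile = config.response_profiles.get(dcr[i])
        patient_intensities.append(_merged_intensities(config.intensities, profile))

    features = _resolve_features(config, master, patient_intensities)
    spec = config.survival
    lp = np.zeros(config.n_patients)
    for name, coef in spec.coefficients.items():
        lp += coef * features[name]

    samples: list[SampleSet] = []
    survival: list[SurvivalRecord] = []
    panel_ids = sorted(config.intensities)
    for i, pid in enumerate(patient_ids):
        sample_id = f"S{i + 1:02d}"
        fields: list[FieldTable] = []
        for p_idx, panel_id in enumerate(panel_ids):
            for f_idx in range(config.n_fields_per_patient):
                ss = np.random.SeedSequence(config.seed, spawn_key=(1, i, p_idx, f_idx))
                fields.append(
                    simulate_field(
                        config,
                        patient_profile=patient_intensities[i],
                        seed=ss,
                        panel_id=panel_id,
                        field_id=f"{sample_id}_{panel_id}_f{f_idx + 1:02d}",
                        sample_id=sample_id,
                    )
                )
        # survival outcome
        rate = spec.baseline_hazard * math.exp(lp[i])
        t_event = master.exponential(1.0 / rate)
        time, event = t_event, True
        if spec.horizon_months is not None and t_event > spec.horizon_months:
            time, event = spec.horizon_months, False
        # independent uniform censoring over [0, cap], Bernoulli-thinned to the
        # requested rate; independence of the censoring time from the event
        # time preserves the proportional-hazards structure
        if spec.censoring_rate > 0:
            exposed = master.random() < spec.censoring_rate
            cap = (
                spec.horizon_months
                if spec.horizon_months is not None
                else math.log(100.0) / spec.baseline_hazard
            )
            c_time = master.uniform(0.0, cap)
            if exposed and c_time < time:
                time, event = c_time, False
        time = max(time, 1e-9)  # survival times are strictly positive
        clinical = ClinicalRecord(
            patient_id=pid,
            metastasis_site=sites[i],
            recist=responses[i],
            os_months=time,
            event=event,
            treatment_class=treatments[i],
            tls_present=tls[i],
        )
        samples.append(SampleSet(sample_id, pid, sites[i], fields, clinical))
        survival.append(
            SurvivalRecord(
                pid,
                time,
                event,
                groups={
                    "dcr_group": dcr[i],
                    "site": sites[i],
                    "treatment_class": treatments[i],
                    "tls_present": tls[i],
                    "vital_status": "dead" if event else "alive",
                },
            )
        )

    truth = CohortGroundTruth(
        patient_ids=patient_ids,
        intensities={pid: patient_intensities[i] for i, pid in enumerate(patient_ids)},
        attracted_fractions={
            (s.panel_id, s.target, s.anchor): s.attracted_fraction
            for s in config.proximity_spec
        },
        coefficients=dict(spec.coefficients),
        features={
            name: {pid: float(vals[i]) for i, pid in enumerate(patient_ids)}
            for name, vals in features.items()
        },
        groups={
            pid: {
                "recist": responses[i],
                "dcr_group": dcr[i],
                "site": sites[i],
                "treatment_class": treatments[i],
                "tls_present": tls[i],
            }
            for i, pid in enumerate(patient_ids)
        },
    )
    return samples, survival, truth


def write_ground_truth(truth: CohortGroundTruth, path: str | Path) -> None:
    """Write the per-patient ground truth as a long-format TSV."""
    rows = []
    for pid in truth.patient_ids:
        for panel_id, arch_map in truth.intensities[pid].items():
            for name, (lam_t, lam_s) in sorted(arch_map.items()):
                rows.append(
                    {
                        "patient_id": pid,
                        "panel_id": panel_id,
                        "archetype": name,
                        "lambda_tumor": lam_t,
                        "lambda_stroma": lam_s,
                        **truth.groups[pid],
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
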