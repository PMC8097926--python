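"""End-to-end orchestration: simulate or ingest a cohort, compute the full
metric catalogue, run group comparisons, correlations and survival
stratifications, and write a reproducible report.

Metric keys
-----------
Every per-patient metric is addressed by a compact string key:

* ``density|<phenotype>|<compartment>`` — cells/mm² (compartment
  ``tumor``, ``stroma`` or ``total``);
* ``pct|<phenotype>|<parent>|<compartment>`` — percentage of the phenotype
  among the parent population (``all`` = all phenotyped immune cells);
* ``nn|<reference>|<target>`` — nearest-neighbor mean distance in µm;
* ``fwr|<reference>|<target>|<radius>`` — % of reference cells within the
  radius (µm) of a target cell;
* ``ratio|<name>`` — ratio of two other metric keys (e.g. CD8/CD4, the
  intra-tumoral/peri-tumoral ratio).

The default configuration reproduces the standard metastatic-melanoma
contexture catalogue: densities and percentages per compartment for both
panels, the CD8/CD4 ratio, the I/P ratio of %CD8+GrzB+, Treg/CTL ratios,
nearest-neighbor distances tumor→CD3 and tumor→CD8, fraction-within at
20/25/30 µm for the canonical pairs, the Immunoscore and the CD3/CD68
concordance groups.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field as dc_field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .errors import ConfigError
from .io import (
    STROMA,
    TUMOR,
    ClinicalRecord,
    ColumnMapping,
    SampleSet,
    assemble_sample,
    read_area_sidecar,
    read_cell_table,
    read_clinical_table,
    write_cell_table,
)
from .panels import DEFAULT_PANELS, PanelDefinition, TUMOR_LABEL, phenotype_panel
from .phenotyping import (
    TOTAL,
    assign_phenotypes,
    compartment_density,
    phenotype_percentage,
)
from .scores import (
    CONTROLLED,
    HIGH,
    classify_response,
    compute_immunoscore,
    concordance_group,
    dichotomize_by_median,
    ratio_metric,
)
from .simulate import (
    ProximityPlacement,
    SimulationConfig,
    SurvivalSpec,
    simulate_cohort,
    write_ground_truth,
)
from .spatial import ProximityMetricSpec, aggregate_spatial_metric
from .stats import (
    SurvivalRecord,
    cox_hazard_ratio,
    kaplan_meier,
    logrank_test,
    mann_whitney_test,
    multigroup_logrank_test,
    spearman_correlation,
)

logger = logging.getLogger("immunocontexture")

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "default_simulation_config",
    "default_config",
    "load_config",
    "run_pipeline",
    "generate_report",
]

KNOWN_GROUPINGS = ("dcr_group", "site", "treatment_class", "vital_status", "tls_present")

IMMUNOSCORE_KEYS = (
    "density|CD3|tumor",
    "density|CD3|stroma",
    "density|CD8|tumor",
    "density|CD8|stroma",
)
CONCORDANCE_KEYS = ("density|CD3|tumor", "density|CD68|tumor")


@dataclass
class IngestPaths:
    """File inputs for ingest mode."""

    cell_tables: Sequence[str]  # paths to per-field cell tables
    clinical_path: str
    mapping: ColumnMapping | None = None
    areas_path: str | None = None
    scale_um_per_px: float = 1.0
    sample_of_patient: Mapping[str, str] | None = None  # sample_id -> patient_id


@dataclass
class AnalysisConfig:
    """Single source of truth for one pipeline run."""

    mode: str = "simulate"  # simulate | ingest
    simulation: SimulationConfig | None = None
    ingest: IngestPaths | None = None
    panels: Mapping[str, PanelDefinition] = dc_field(
        default_factory=lambda: dict(DEFAULT_PANELS)
    )
    metrics: Sequence[str] = ()
    ratios: Mapping[str, tuple[str, str]] = dc_field(default_factory=dict)
    correlations: Sequence[tuple[str, str]] = ()
    groupings: Sequence[str] = ("dcr_group", "site", "treatment_class", "vital_status")
    survival_metrics: Sequence[str] = ()
    immunoscore: bool = True
    concordance: bool = True
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def all_metric_keys(self) -> list[str]:
        keys = list(self.metrics)
        keys += [f"ratio|{name}" for name in self.ratios]
        return keys

    def validate(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate" and self.simulation is None:
            raise ConfigError("simulate mode requires a simulation config")
        if self.mode == "ingest" and self.ingest is None:
            raise ConfigError("ingest mode requires ingest paths")
        defined_phenotypes = {TUMOR_LABEL}
        for panel in self.panels.values():
            defined_phenotypes.update(panel.phenotype_names)
        for key in self.metrics:
            spec = parse_metric_key(key)
            for phen in spec["phenotypes"]:
                if phen not in defined_phenotypes and phen != "all":
                    raise ConfigError(
                        f"metric {key!r} references undefined phenotype {phen!r}"
                    )
        defined = set(self.all_metric_keys())
        for name, (num, den) in self.ratios.items():
            for ref in (num, den):
                if ref not in defined:
                    raise ConfigError(
                        f"ratio {name!r} references undefined metric {ref!r}"
                    )
        for a, b in self.correlations:
            for ref in (a, b):
                if ref not in defined:
                    raise ConfigError(f"correlation references undefined metric {ref!r}")
        for key in self.survival_metrics:
            if key not in defined:
                raise ConfigError(f"survival analysis references undefined metric {key!r}")
        for g in self.groupings:
            if g not in KNOWN_GROUPINGS:
                raise ConfigError(
                    f"unknown grouping {g!r}; allowed: {list(KNOWN_GROUPINGS)}"
                )


def parse_metric_key(key: str) -> dict:
    """Decompose a metric key; raises ConfigError for malformed keys."""
    parts = key.split("|")
    try:
        if parts[0] == "density" and len(parts) == 3:
            if parts[2] not in (TUMOR, STROMA, TOTAL):
                raise ConfigError(f"metric {key!r}: unknown compartment {parts[2]!r}")
            return {"kind": "density", "phenotypes": [parts[1]], "compartment": parts[2]}
        if parts[0] == "pct" and len(parts) == 4:
            if parts[3] not in (TUMOR, STROMA, TOTAL):
                raise ConfigError(f"metric {key!r}: unknown compartment {parts[3]!r}")
            return {
                "kind": "pct",
                "phenotypes": [parts[1]] + ([] if parts[2] == "all" else [parts[2]]),
                "parent": None if parts[2] == "all" else parts[2],
                "compartment": parts[3],
            }
        if parts[0] == "nn" and len(parts) == 3:
            return {"kind": "nn", "phenotypes": [parts[1], parts[2]]}
        if parts[0] == "fwr" and len(parts) == 4:
            return {
                "kind": "fwr",
                "phenotypes": [parts[1], parts[2]],
                "radius": float(parts[3]),
            }
    except (IndexError, ValueError) as exc:
        raise ConfigError(f"malformed metric key {key!r}") from exc
    raise ConfigError(f"malformed metric key {key!r}")


def _infer_spatial_panel(reference: str, target: str) -> str | None:
    return phenotype_panel(target) or phenotype_panel(reference)


# ---------------------------------------------------------------------------
# default study preset


def default_simulation_config(seed: int = 0) -> SimulationConfig:
    """A 21-patient two-panel cohort with PD/CD contexture differences.

    Intensities are in cells/mm² and chosen as realistic multiplex-IHC
    magnitudes for melanoma metastases: tumor cells dominate the tumor
    compartment, T cells and macrophages dominate the infiltrate, NK cells
    and neutrophils are negligible. Controlled-disease (CD) patients get
    more cytotoxic and fewer regulatory/M2 cells than progressive-disease
    (PD) patients; a proximity layer places a fraction of T cells near
    tumor cells. Survival is tied to the true intra-tumoral activated-CTL
    intensity through a proportional-hazards coefficient.
    """
    base = {
        "panel1": {
            "tumor": (900.0, 40.0),
            "CD3": (150.0, 250.0),
            "CD20": (20.0, 60.0),
            "CD68": (220.0, 110.0),
            "CD56": (4.0, 6.0),
            "NE": (4.0, 8.0),
        },
        "panel2": {
            "tumor": (900.0, 40.0),
            "CD8": (110.0, 170.0),
            "CD4": (80.0, 120.0),
            "Treg": (22.0, 40.0),
            "CD8_GrzB": (35.0, 30.0),
            "CD4_GrzB": (5.0, 8.0),
            "CD163": (160.0, 80.0),
        },
    }
    cd_profile = {
        "panel2": {
            "CD8": (170.0, 220.0),
            "CD8_GrzB": (60.0, 35.0),
            "Treg": (14.0, 26.0),
            "CD163": (110.0, 60.0),
        },
        "panel1": {"CD68": (180.0, 100.0)},
    }
    pd_profile = {
        "panel2": {
            "CD8": (70.0, 120.0),
            "CD8_GrzB": (18.0, 25.0),
            "Treg": (36.0, 60.0),
            "CD163": (230.0, 120.0),
        },
        "panel1": {"CD68": (260.0, 130.0)},
    }
    return SimulationConfig(
        intensities=base,
        n_patients=21,
        n_fields_per_patient=20,
        response_counts={"PD": 7, "SD": 7, "PR": 6, "CR": 1},
        response_profiles={CONTROLLED: cd_profile, "PD": pd_profile},
        proximity_spec=(
            ProximityPlacement("CD3", "tumor", 0.30, 20.0, "panel1"),
            ProximityPlacement("CD8", "tumor", 0.30, 20.0, "panel2"),
        ),
        survival=SurvivalSpec(
            baseline_hazard=1.0 / 40.0,
            coefficients={"density:panel2:CD8_GrzB:tumor": -0.4},
            censoring_rate=0.35,
            horizon_months=171.0,
        ),
        seed=seed,
    )


def default_config(seed: int = 0, output_dir: str = "results") -> AnalysisConfig:
    """The default analysis preset covering the full metric catalogue."""
    metrics: list[str] = []
    for phen in ("CD20", "CD3", "CD68", "CD56", "NE", "CD4", "CD8", "Treg",
                 "CD8_GrzB", "CD4_GrzB", "CD163"):
        for comp in (TUMOR, STROMA, TOTAL):
            metrics.append(f"density|{phen}|{comp}")
        for comp in (TUMOR, STROMA):
            metrics.append(f"pct|{phen}|all|{comp}")
    for comp in (TUMOR, STROMA, TOTAL):
        metrics.append(f"pct|CD8_GrzB|CD8|{comp}")
        metrics.append(f"pct|Treg|CD4|{comp}")
    metrics += [
        "nn|tumor|CD3",
        "nn|tumor|CD8",
        "fwr|tumor|CD8|20",
        "fwr|tumor|CD8|25",
        "fwr|tumor|CD8_GrzB|30",
        "fwr|tumor|CD163|20",
        "fwr|CD8|CD163|20",
    ]
    ratios = {
        "CD8_CD4_tumor": ("density|CD8|tumor", "density|CD4|tumor"),
        "CD8_CD4_stroma": ("density|CD8|stroma", "density|CD4|stroma"),
        "IP_CD8_GrzB_pct": ("pct|CD8_GrzB|CD8|tumor", "pct|CD8_GrzB|CD8|stroma"),
        "Treg_CD8GrzB_tumor": ("density|Treg|tumor", "density|CD8_GrzB|tumor"),
        "Treg_CD8GrzB_total": ("density|Treg|total", "density|CD8_GrzB|total"),
        "Treg_CD8_stroma": ("density|Treg|stroma", "density|CD8|stroma"),
    }
    correlations = [
        ("density|CD4|tumor", "density|Treg|tumor"),
        ("density|CD4|tumor", "density|CD4_GrzB|tumor"),
        ("density|CD3|tumor", "density|CD68|tumor"),
        ("density|CD3|stroma", "density|CD68|stroma"),
        ("density|CD3|tumor", "density|CD20|tumor"),
    ]
    survival_metrics = [
        "pct|CD8_GrzB|CD8|total",
        "pct|CD8_GrzB|CD8|tumor",
        "density|Treg|stroma",
        "ratio|Treg_CD8_stroma",
        "pct|Treg|CD4|tumor",
        "pct|Treg|CD4|stroma",
    ]
    return AnalysisConfig(
        mode="simulate",
        simulation=default_simulation_config(seed),
        metrics=metrics,
        ratios=ratios,
        correlations=correlations,
        survival_metrics=survival_metrics,
        output_dir=output_dir,
        seed=seed,
    )


def load_config(path: str | Path) -> AnalysisConfig:
    """Build an AnalysisConfig from a YAML file layered over the defaults.

    Recognized top-level keys: ``mode``, ``seed``, ``output_dir``,
    ``metrics``, ``ratios``, ``correlations``, ``groupings``,
    ``survival_metrics``, ``immunoscore``, ``concordance``, ``simulation``
    (scalar SimulationConfig overrides) and ``ingest``.
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path}: expected a mapping at top level")
    seed = int(raw.get("seed", 0))
    cfg = default_config(seed=seed, output_dir=raw.get("output_dir", "results"))
    simple = {
        "mode": str,
        "log_level": str,
        "immunoscore": bool,
        "concordance": bool,
    }
    for key, cast in simple.items():
        if key in raw:
            cfg = replace(cfg, **{key: cast(raw[key])})
    for key in ("metrics", "groupings", "survival_metrics"):
        if key in raw:
            cfg = replace(cfg, **{key: list(raw[key])})
    if "ratios" in raw:
        cfg = replace(
            cfg, ratios={k: tuple(v) for k, v in dict(raw["ratios"]).items()}
        )
    if "correlations" in raw:
        cfg = replace(cfg, correlations=[tuple(p) for p in raw["correlations"]])
    if "simulation" in raw:
        sim_over = dict(raw["simulation"])
        surv_over = sim_over.pop("survival", None)
        sim = replace(cfg.simulation, **sim_over)
        if surv_over:
            sim = replace(sim, survival=replace(sim.survival, **surv_over))
        cfg = replace(cfg, simulation=sim)
    if "ingest" in raw:
        ing = dict(raw["ingest"])
        cfg = replace(cfg, ingest=IngestPaths(**ing), mode=raw.get("mode", "ingest"))
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# bundle


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run, plus the run manifest."""

    patient_metrics: pd.DataFrame  # long: patient_id, metric, value, n_fields...
    metric_wide: pd.DataFrame  # patients × metric keys
    group_comparisons: pd.DataFrame
    correlation_table: pd.DataFrame
    survival_table: pd.DataFrame
    km_curves: pd.DataFrame
    immunoscore_table: pd.DataFrame
    score_labels: pd.DataFrame  # per-patient dichotomization labels / groups
    manifest: dict
    errors: list[str]
    survival_records: list[SurvivalRecord]

    @property
    def n_patients(self) -> int:
        return int(self.metric_wide.shape[0])


def _config_hash(config: AnalysisConfig) -> str:
    def default(o):
        if isinstance(o, frozenset):
            return sorted(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _ingest_cohort(
    config: AnalysisConfig,
) -> tuple[list[SampleSet], list[SurvivalRecord]]:
    ing = config.ingest
    clinical = read_clinical_table(ing.clinical_path)
    areas = read_area_sidecar(ing.areas_path) if ing.areas_path else {}
    fields_by_sample: dict[str, list] = {}
    for p in ing.cell_tables:
        table = read_cell_table(
            p,
            mapping=ing.mapping,
            scale_um_per_px=ing.scale_um_per_px,
            compartment_areas=areas.get(Path(p).stem),
        )
        fields_by_sample.setdefault(table.sample_id, []).append(table)
    sample_of_patient = ing.sample_of_patient or {}
    samples = []
    survival = []
    for sample_id in sorted(fields_by_sample):
        pid = sample_of_patient.get(sample_id, sample_id)
        clin = clinical.get(pid)
        if clin is None:
            raise ConfigError(f"no clinical record for patient {pid!r}")
        samples.append(assemble_sample(fields_by_sample[sample_id], clin))
        label = classify_response(clin.recist, pid)
        survival.append(
            SurvivalRecord(
                pid,
                clin.os_months,
                clin.event,
                groups={
                    "dcr_group": label.dcr_group,
                    "site": clin.metastasis_site,
                    "treatment_class": clin.treatment_class,
                    "tls_present": clin.tls_present,
                    "vital_status": "dead" if clin.event else "alive",
                },
            )
        )
    return samples, survival


def _compute_metric(sample: SampleSet, key: str):
    spec = parse_metric_key(key)
    if spec["kind"] == "density":
        rec = compartment_density(sample, spec["phenotypes"][0], spec["compartment"])
        return rec.value, rec.n_fields_used, rec.n_fields_excluded
    if spec["kind"] == "pct":
        rec = phenotype_percentage(
            sample, spec["phenotypes"][0], spec["parent"], spec["compartment"]
        )
        return rec.value, rec.n_fields_used, rec.n_fields_excluded
    ref, tgt = spec["phenotypes"]
    pspec = ProximityMetricSpec(
        metric="nn_mean_distance" if spec["kind"] == "nn" else "fraction_within",
        reference=ref,
        target=tgt,
        radius_um=spec.get("radius"),
        panel_id=_infer_spatial_panel(ref, tgt),
    )
    res = aggregate_spatial_metric(sample, pspec)
    return res.patient_value, res.n_fields_used, res.n_fields_excluded


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Run the full analysis; deterministic for a fixed seed in simulate
    mode. Failures in individual metrics are collected into the error
    ledger instead of aborting the run."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    t0 = time.time()
    errors: list[str] = []

    if config.mode == "simulate":
        sim = replace(config.simulation, seed=config.seed)
        samples, survival, truth = simulate_cohort(sim)
    else:
        samples, survival = _ingest_cohort(config)
        truth = None
    if not samples:
        raise ConfigError("empty cohort: nothing to analyze")
    logger.info("cohort ready: %d patients, %.1fs", len(samples), time.time() - t0)

    # phenotype every field through its panel definition
    for sample in samples:
        sample.fields = [
            assign_phenotypes(f, config.panels[f.panel_id])
            if f.panel_id in config.panels
            else f
            for f in sample.fields
        ]

    # per-patient metrics
    metric_keys = list(config.metrics)
    if config.immunoscore:
        metric_keys += [k for k in IMMUNOSCORE_KEYS if k not in metric_keys]
    if config.concordance:
        metric_keys += [k for k in CONCORDANCE_KEYS if k not in metric_keys]
    rows = []
    wide: dict[str, dict[str, float]] = {}
    for sample in samples:
        pid = sample.patient_id
        wide[pid] = {}
        for key in metric_keys:
            try:
                value, n_used, n_excl = _compute_metric(sample, key)
            except Exception as exc:  # collected, not fatal
                errors.append(f"metric {key} / patient {pid}: {exc}")
                value, n_used, n_excl = float("nan"), 0, 0
            rows.append(
                {
                    "patient_id": pid,
                    "metric": key,
                    "value": value,
                    "n_fields_used": n_used,
                    "n_fields_excluded": n_excl,
                }
            )
            wide[pid][key] = value
    for pid in wide:
        for name, (num, den) in config.ratios.items():
            try:
                val = ratio_metric(wide[pid][num], wide[pid][den])
            except Exception as exc:
                errors.append(f"ratio {name} / patient {pid}: {exc}")
                val = float("nan")
            wide[pid][f"ratio|{name}"] = val
            rows.append(
                {
                    "patient_id": pid,
                    "metric": f"ratio|{name}",
                    "value": val,
                    "n_fields_used": 0,
                    "n_fields_excluded": 0,
                }
            )
    patient_metrics = pd.DataFrame(rows)
    metric_wide = pd.DataFrame(wide).T.sort_index()
    metric_wide.index.name = "patient_id"
    logger.info("metrics done: %d keys, %.1fs", len(metric_keys), time.time() - t0)

    groups_by_patient = {r.patient_id: r.groups for r in survival}

    # group comparisons: Mann-Whitney for every metric × grouping
    cmp_rows = []
    for grouping in config.groupings:
        labels = {p: g.get(grouping) for p, g in groups_by_patient.items()}
        levels = sorted({str(v) for v in labels.values() if v is not None})
        if len(levels) != 2:
            errors.append(f"grouping {grouping}: expected 2 levels, found {levels}")
            continue
        for key in metric_wide.columns:
            x = [
                metric_wide.loc[p, key]
                for p in metric_wide.index
                if str(labels[p]) == levels[0] and not math.isnan(metric_wide.loc[p, key])
            ]
            y = [
                metric_wide.loc[p, key]
                for p in metric_wide.index
                if str(labels[p]) == levels[1] and not math.isnan(metric_wide.loc[p, key])
            ]
            if not x or not y:
                errors.append(f"comparison {key} by {grouping}: empty group")
                continue
            res = mann_whitney_test(x, y)
            cmp_rows.append(
                {
                    "metric": key,
                    "grouping": grouping,
                    "group1": levels[0],
                    "group2": levels[1],
                    "n1": res.n1,
                    "n2": res.n2,
                    "median1": float(np.median(x)),
                    "median2": float(np.median(y)),
                    "U": res.statistic,
                    "p": res.p_two_sided,
                    "method": res.method,
                }
            )
    group_comparisons = pd.DataFrame(cmp_rows)

    # Spearman correlations, full cohort and per DCR group
    corr_rows = []
    dcr_labels = {p: g.get("dcr_group") for p, g in groups_by_patient.items()}
    subsets = {"all": list(metric_wide.index)}
    for level in sorted({str(v) for v in dcr_labels.values() if v is not None}):
        subsets[f"dcr={level}"] = [p for p in metric_wide.index if str(dcr_labels[p]) == level]
    for a, b in config.correlations:
        for subset_name, pids in subsets.items():
            xy = [
                (metric_wide.loc[p, a], metric_wide.loc[p, b])
                for p in pids
                if not (math.isnan(metric_wide.loc[p, a]) or math.isnan(metric_wide.loc[p, b]))
            ]
            if len(xy) < 4:
                continue
            x, y = zip(*xy)
            try:
                res = spearman_correlation(x, y)
            except Exception as exc:
                errors.append(f"correlation {a} vs {b} [{subset_name}]: {exc}")
                continue
            corr_rows.append(
                {
                    "metric_x": a,
                    "metric_y": b,
                    "subset": subset_name,
                    "n": res.n,
                    "r": res.r,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                }
            )
    correlation_table = pd.DataFrame(corr_rows)

    # survival stratification
    surv_rows = []
    km_rows = []
    label_rows = []
    surv_by_pid = {r.patient_id: r for r in survival}

    def km_to_rows(analysis: str, stratum: str, recs: list[SurvivalRecord]):
        curve = kaplan_meier(recs)
        for t, s in zip(curve.times, curve.survival):
            km_rows.append(
                {"analysis": analysis, "stratum": stratum, "time": t, "survival": s}
            )
        return curve

    def median_split_analysis(key: str):
        values = {p: float(metric_wide.loc[p, key]) for p in metric_wide.index}
        labels, rule = dichotomize_by_median(values, metric=key)
        for pid in sorted(labels):
            label_rows.append(
                {"patient_id": pid, "score": f"split|{key}", "label": labels[pid]}
            )
        hi = [surv_by_pid[p] for p in sorted(labels) if labels[p] == HIGH]
        lo = [surv_by_pid[p] for p in sorted(labels) if labels[p] == "low"]
        if not hi or not lo:
            errors.append(f"survival {key}: degenerate median split")
            return
        c_hi = km_to_rows(key, "high", hi)
        c_lo = km_to_rows(key, "low", lo)
        lr = logrank_test(hi, lo)
        recs = hi + lo
        cov = [1.0] * len(hi) + [0.0] * len(lo)
        cox = cox_hazard_ratio(recs, cov)
        surv_rows.append(
            {
                "analysis": key,
                "comparison": "high_vs_low",
                "median_cutoff": rule.median,
                "n_high": len(hi),
                "n_low": len(lo),
                "median_os_high": c_hi.median,
                "median_os_low": c_lo.median,
                "logrank_chi2": lr.chi2,
                "logrank_p": lr.p,
                "hr": cox.hr,
                "hr_ci_low": cox.ci_low,
                "hr_ci_high": cox.ci_high,
                "hr_p": cox.p,
                "separation": cox.separation,
            }
        )

    for key in config.survival_metrics:
        try:
            median_split_analysis(key)
        except Exception as exc:
            errors.append(f"survival {key}: {exc}")

    # Immunoscore
    immunoscore_rows = []
    if config.immunoscore:
        try:
            dens = [
                {p: float(metric_wide.loc[p, k]) for p in metric_wide.index}
                for k in IMMUNOSCORE_KEYS
            ]
            iscore = compute_immunoscore(*dens)
            for pid in sorted(iscore):
                r = iscore[pid]
                immunoscore_rows.append(
                    {
                        "patient_id": pid,
                        **{k: r.indicators.get(k) for k in
                           ("cd3_tumor", "cd3_stroma", "cd8_tumor", "cd8_stroma")},
                        "score": r.score,
                        "class": r.immunoscore_class,
                    }
                )
            classed = {p: r.immunoscore_class for p, r in iscore.items() if r.score is not None}
            strata = sorted(set(classed.values()))
            recs = [surv_by_pid[p] for p in sorted(classed)]
            labs = [classed[p] for p in sorted(classed)]
            if len(strata) >= 2:
                lr = multigroup_logrank_test(recs, labs)
                for s in strata:
                    km_to_rows("immunoscore", s, [surv_by_pid[p] for p in sorted(classed) if classed[p] == s])
                row = {
                    "analysis": "immunoscore",
                    "comparison": "|".join(strata),
                    "median_cutoff": float("nan"),
                    "n_high": sum(1 for v in labs if v == "I4"),
                    "n_low": sum(1 for v in labs if v == "I0"),
                    "median_os_high": None,
                    "median_os_low": None,
                    "logrank_chi2": lr.chi2,
                    "logrank_p": lr.p,
                    "hr": float("nan"),
                    "hr_ci_low": float("nan"),
                    "hr_ci_high": float("nan"),
                    "hr_p": float("nan"),
                    "separation": False,
                }
                # pairwise IntI vs extremes where present
                if "IntI" in strata:
                    for other in ("I0", "I4"):
                        if other not in strata:
                            continue
                        pair = [
                            surv_by_pid[p]
                            for p in sorted(classed)
                            if classed[p] in ("IntI", other)
                        ]
                        cov = [
                            1.0 if classed[r.patient_id] == "IntI" else 0.0 for r in pair
                        ]
                        try:
                            cox = cox_hazard_ratio(pair, cov)
                            surv_rows.append(
                                {
                                    "analysis": "immunoscore",
                                    "comparison": f"IntI_vs_{other}",
                                    "median_cutoff": float("nan"),
                                    "n_high": int(sum(cov)),
                                    "n_low": int(len(cov) - sum(cov)),
                                    "median_os_high": None,
                                    "median_os_low": None,
                                    "logrank_chi2": float("nan"),
                                    "logrank_p": float("nan"),
                                    "hr": cox.hr,
                                    "hr_ci_low": cox.ci_low,
                                    "hr_ci_high": cox.ci_high,
                                    "hr_p": cox.p,
                                    "separation": cox.separation,
                                }
                            )
                        except Exception as exc:
                            errors.append(f"immunoscore IntI vs {other}: {exc}")
                surv_rows.append(row)
            for pid in sorted(classed):
                label_rows.append(
                    {"patient_id": pid, "score": "immunoscore", "label": classed[pid]}
                )
        except Exception as exc:
            errors.append(f"immunoscore: {exc}")
    immunoscore_table = pd.DataFrame(immunoscore_rows)

    # CD3/CD68 concordance groups (intra-tumoral densities)
    if config.concordance:
        try:
            cd3 = {p: float(metric_wide.loc[p, CONCORDANCE_KEYS[0]]) for p in metric_wide.index}
            cd68 = {p: float(metric_wide.loc[p, CONCORDANCE_KEYS[1]]) for p in metric_wide.index}
            l3, _ = dichotomize_by_median(cd3, metric=CONCORDANCE_KEYS[0])
            l68, _ = dichotomize_by_median(cd68, metric=CONCORDANCE_KEYS[1])
            grp = {p: concordance_group(l3[p], l68[p]) for p in sorted(cd3)}
            for pid in sorted(grp):
                label_rows.append(
                    {"patient_id": pid, "score": "cd3_cd68_concordance", "label": grp[pid]}
                )
            conc = [surv_by_pid[p] for p in sorted(grp) if grp[p] == "concordant"]
            disc = [surv_by_pid[p] for p in sorted(grp) if grp[p] == "discordant"]
            if conc and disc:
                c_c = km_to_rows("cd3_cd68_concordance", "concordant", conc)
                c_d = km_to_rows("cd3_cd68_concordance", "discordant", disc)
                lr = logrank_test(conc, disc)
                cox = cox_hazard_ratio(
                    conc + disc, [1.0] * len(conc) + [0.0] * len(disc)
                )
                surv_rows.append(
                    {
                        "analysis": "cd3_cd68_concordance",
                        "comparison": "concordant_vs_discordant",
                        "median_cutoff": float("nan"),
                        "n_high": len(conc),
                        "n_low": len(disc),
                        "median_os_high": c_c.median,
                        "median_os_low": c_d.median,
                        "logrank_chi2": lr.chi2,
                        "logrank_p": lr.p,
                        "hr": cox.hr,
                        "hr_ci_low": cox.ci_low,
                        "hr_ci_high": cox.ci_high,
                        "hr_p": cox.p,
                        "separation": cox.separation,
                    }
                )
        except Exception as exc:
            errors.append(f"concordance: {exc}")

    survival_table = pd.DataFrame(surv_rows)
    km_curves = pd.DataFrame(km_rows)
    score_labels = pd.DataFrame(label_rows)

    manifest = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "mode": config.mode,
        "config_hash": _config_hash(config),
        "n_patients": len(samples),
        "n_fields": sum(len(s.fields) for s in samples),
        "n_metrics": len(metric_keys) + len(config.ratios),
        "n_errors": len(errors),
    }
    logger.info("pipeline done in %.1fs (%d soft errors)", time.time() - t0, len(errors))
    return ReportBundle(
        patient_metrics=patient_metrics,
        metric_wide=metric_wide,
        group_comparisons=group_comparisons,
        correlation_table=correlation_table,
        survival_table=survival_table,
        km_curves=km_curves,
        immunoscore_table=immunoscore_table,
        score_labels=score_labels,
        manifest=manifest,
        errors=errors,
        survival_records=survival,
    )


def generate_report(
    bundle: ReportBundle, output_dir: str | Path, *, plots: bool = False
) -> Path:
    """Write the bundle as TSV tables plus a human-readable summary.

    Optionally renders Kaplan-Meier step plots (one PNG per survival
    analysis) from the exported curve table.
    """
    if bundle.n_patients == 0:
        raise ValueError("empty bundle: nothing to report")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.patient_metrics.to_csv(out / "patient_metrics.tsv", sep="\t", index=False)
    bundle.metric_wide.to_csv(out / "patient_metrics_wide.tsv", sep="\t")
    bundle.group_comparisons.to_csv(out / "group_comparisons.tsv", sep="\t", index=False)
    bundle.correlation_table.to_csv(out / "correlations.tsv", sep="\t", index=False)
    bundle.survival_table.to_csv(out / "survival.tsv", sep="\t", index=False)
    bundle.km_curves.to_csv(out / "km_curves.tsv", sep="\t", index=False)
    bundle.immunoscore_table.to_csv(out / "immunoscore.tsv", sep="\t", index=False)
    bundle.score_labels.to_csv(out / "score_labels.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    with open(out / "errors.log", "w", encoding="utf-8") as fh:
        fh.write("\n".join(bundle.errors))

    lines = [
        "immune contexture analysis summary",
        "==================================",
        f"patients: {bundle.n_patients}",
        f"metrics per patient: {bundle.metric_wide.shape[1]}",
        f"group comparisons: {len(bundle.group_comparisons)}",
        f"correlations: {len(bundle.correlation_table)}",
        f"survival analyses: {len(bundle.survival_table)}",
        f"soft errors: {len(bundle.errors)}",
        "",
    ]
    if len(bundle.group_comparisons):
        sig = bundle.group_comparisons[bundle.group_comparisons["p"] <= 0.05]
        lines.append(f"comparisons with p <= 0.05: {len(sig)}")
        for r in sig.itertuples(index=False):
            lines.append(
                f"  {r.metric} by {r.grouping}: median {r.median1:.3g} vs "
                f"{r.median2:.3g}, U={r.U:g}, p={r.p:.4f}"
            )
    if len(bundle.survival_table):
        lines.append("")
        lines.append("survival stratifications:")
        for r in bundle.survival_table.itertuples(index=False):
            lines.append(
                f"  {r.analysis} [{r.comparison}]: HR={r.hr:.3g} "
                f"(95% CI {r.hr_ci_low:.3g}-{r.hr_ci_high:.3g}), "
                f"log-rank p={r.logrank_p:.4f}"
            )
    with open(out / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")

    if plots and len(bundle.km_curves):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for analysis, sub in bundle.km_curves.groupby("analysis"):
            fig, ax = plt.subplots(figsize=(5, 4))
            for stratum, curve in sub.groupby("stratum"):
                ax.step(curve["time"], curve["survival"], where="post", label=str(stratum))
            ax.set_xlabel("months from metastatic diagnosis")
            ax.set_ylabel("overall survival probability")
            ax.set_ylim(0, 1.02)
            ax.legend()
            ax.set_title(str(analysis))
            safe = str(analysis).replace("|", "_").replace("/", "_")
            fig.tight_layout()
            fig.savefig(out / f"km_{safe}.png", dpi=120)
            plt.close(fig)
    return out


def export_cohort(
    config: SimulationConfig, output_dir: str | Path
) -> Path:
    """Simulate a cohort and write it to disk: per-field cell tables, the
    clinical table and the ground-truth TSV (CLI ``simulate`` verb)."""
    out = Path(output_dir)
    (out / "fields").mkdir(parents=True, exist_ok=True)
    samples, survival, truth = simulate_cohort(config)
    clin_rows = []
    for sample, rec in zip(samples, survival):
        for f in sample.fields:
            write_cell_table(f, out / "fields" / f"{f.field_id}.csv")
        c = sample.clinical
        clin_rows.append(
            {
                "patient_id": c.patient_id,
                "sample_id": sample.sample_id,
                "site": c.metastasis_site,
                "response": c.recist,
                "os_months": c.os_months,
                "event": int(c.event),
                "treatment_class": c.treatment_class,
                "tls_present": int(bool(c.tls_present)),
            }
        )
    pd.DataFrame(clin_rows).to_csv(out / "clinical.tsv", sep="\t", index=False)
    write_ground_truth(truth, out / "ground_truth.tsv")
    return out
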