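# Methods

This note documents the models, conventions and numerical choices behind
the package, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

A **field** is one 20X image tile: a list of segmented cells (continuous
2-D positions in µm, origin at the field top-left, y increasing downward)
plus the areas (mm²) of its two tissue compartments, the tumor region and
the surrounding stroma. Fields are analyzed independently — acquisition
avoids tile overlaps, so cross-field distances are undefined by design and
no stitching into slide coordinates is attempted. A **sample** collects all
fields of one patient, possibly spanning two staining panels cut from
consecutive sections; the panels are never merged cell-wise, since the
"same" cell does not exist on both sections.

Marker positivity is binary on input. Phenotype labels are derived from
marker combinations and are multi-label: a CD8+GranzymeB+ cell carries both
`CD8` and `CD8_GrzB`, so the activated subset is a genuine refinement of
its parent. Cells positive for the melanoma-antibody-cocktail pseudo-marker
are labeled `tumor` and receive no immune labels; double-positives are
treated as tumor cells, because the cocktail's role is to outline the tumor
mass and immune/tumor double-positivity at segmentation boundaries is far
more often bleed-through than biology.

## Densities, percentages, aggregation

Per-field density is count ÷ compartment area (cells/mm²); the `total`
compartment pools counts and areas per field — it is *not* the mean of the
two compartment densities, so large-stroma fields are weighted by area
exactly as the tissue is. Percentages are 100 · count(phenotype ∧ parent) /
count(parent); the default parent (`all`) is all phenotyped immune cells of
the panel in the compartment, a configurable choice since the natural
denominator (all nucleated cells vs all immune cells) is a reporting
convention rather than a measurement.

The patient value of every metric is the **unweighted mean over usable
fields**, matching the per-slide convention for ≥ 20-field 20X acquisitions.
Field exclusion is metric-specific: a field without a tumor region is
excluded from intra-tumoral densities (and tallied) but still contributes
stromal metrics; a field with zero parent cells is excluded from that
percentage. A patient with no usable field yields an explicitly missing
value (NaN plus an exclusion count) — never a silent zero, which would
masquerade as "no infiltrate".

## Proximity metrics

Two phenoptr-style statistics, both 2-D Euclidean and center-to-center
within a single field:

- **nearest-neighbor mean distance**: for each reference cell, the distance
  to the nearest target cell, averaged over reference cells;
- **fraction within radius**: the percentage of reference cells with at
  least one target cell at distance ≤ r. The boundary is inclusive; target
  absence is a valid 0%, not an exclusion. Radii of 20, 25 and 30 µm are
  the presets, bracketing the 25–30 µm center-to-center range at which
  lymphocyte and melanoma cell dimensions imply probable membrane contact.

A cell is never its own neighbor: self-pairs are excluded by cell identity
(not by zero distance, so coincident distinct cells remain legitimate
neighbors). No edge-effect correction is applied; reference cells near the
field border have truncated search ranges, a known small upward bias on
nearest-neighbor distances shared with the upstream convention.
Implementation uses a scipy `cKDTree`; the package's contract is *exact*
floating-point agreement with an O(n·m) brute-force scan, enforced in the
test suite over randomized fields. One subtlety: the oracle writes squared
distances as `dx*dx + dy*dy` — CPython's float power goes through libm
`pow` and can differ from the product by one ulp, which would produce
spurious 1e-15-scale disagreements unrelated to either implementation.

## Scores

- **Median dichotomization**: value > cohort median → high, value ≤ median
  → low. Sending ties to low makes "high" mean *strictly above* the median;
  with it, |low| ≥ |high| always. Medians are computed on the analyzed
  cohort (subgroup analyses recompute subgroup medians). An all-equal
  input degenerates to all-low and emits a warning.
- **Ratios** (CD8/CD4, Treg/CTL, intra-tumoral/peri-tumoral): zero
  denominators yield an explicitly missing value rather than ±∞, because
  downstream rank tests cannot order infinities against each other. The
  I/P ratio defaults to the percentage-based metric (%CD8+GrzB+ among CD8+
  in tumor over the same in stroma); a density-based variant is available
  through the metric-key system.
- **Immunoscore** (median-based variant for small metastatic cohorts): CD3
  and CD8 densities in tumor and stroma, each dichotomized at its own
  cohort median; score = number of highs; class I0 (0), I4 (4), IntI (1–3).
  CD3 comes from the lineage panel and CD8 from the functional panel — the
  only panels carrying them — so the score deliberately crosses sections.
  The colorectal consensus percentile method is out of scope.
- **Concordance groups**: intra-tumoral CD3 and CD68 median labels agree
  (high/high or low/low) → concordant, else discordant.
- **Disease control**: RECIST 1.1 CR/PR/SD → CD, PD → PD; unknown codes are
  rejected rather than guessed.

## Statistics

Mann-Whitney is two-tailed with midranks; the exact null distribution is
used when n₁+n₂ ≤ 12 and the pooled sample is tie-free (≤ 924 arrangements,
deterministic — the regime of small-cohort comparisons), otherwise the
normal approximation with tie and continuity correction. Spearman CIs use
the Fisher z-transform with variance 1.06/(n−3), the standard rank-
correlation adjustment; published CIs from unspecified software may differ
in the third decimal, so only sign and nesting should be compared.
Kaplan-Meier, log-rank (Mantel-Cox) and Cox go through lifelines; Cox uses
Efron tie handling, which degrades more gracefully than Breslow under the
heavy ties that median-split groupings produce. The KM median is the
smallest t with S(t) ≤ 0.5 and is encoded as undefined when never reached.
Complete separation in Cox is flagged and the CI reported unbounded. No
multiple-testing correction is applied anywhere; p-values are raw, and
p ≤ 0.05 is the nominal significance convention.

## Synthetic cohorts

The simulator emulates the *structure* of a two-panel mIHC study — not its
images. Defaults define the study conditions: 21 patients, 20 fields per
panel per patient, 669 × 500 µm fields (a typical 20X tile for the imaging
platform; the true physical tile size is a platform convention, not a
measured quantity), response distribution PD 7 / SD 7 / PR 6 / CR 1, 17/21
liver metastases, 13/21 immunotherapy-treated, 6/21 TLS-positive, and a
171-month follow-up horizon. Intensity magnitudes (cells/mm²) are set once
at realistic levels for melanoma metastases — tumor cells ~900/mm² in the
tumor compartment, T-cell subsets in the tens-to-hundreds, NK cells and
neutrophils negligible — with controlled-disease patients given more
cytotoxic and fewer regulatory/M2 cells than progressive-disease patients.

**Geometry.** Tumor nests are discs with uniformly random (or explicit)
centers, clipped at the field border and unioned when overlapping. The
tumor mask is rasterized at 1 µm with the pixel-center rule, and cells are
placed uniformly *over the same raster*: the recorded compartment area is
exactly the measure from which positions are drawn, so realized density is
an unbiased estimator of the configured intensity by construction. (An
analytic-area branch was considered and rejected: it would decouple the
placement measure from the recorded denominator and re-introduce a
perimeter-scale bias.)

**Proximity layer.** For each (target, anchor, f, r) entry, each target
cell is independently re-placed with probability f, uniformly within a
disc of radius r around a uniformly chosen anchor (rejection-sampled to
stay inside the field). Re-placed cells get their compartment re-assigned
from the mask — attraction toward tumor-cell anchors therefore *raises*
intra-tumoral density of the attracted population above its nominal λ,
a deliberate coupling that mirrors real infiltration. With anchors present
and negligible chance proximity, the downstream fraction-within at radius r
equals 100·f in expectation; recovery tests use dense anchors (≈10 per
field) at a small radius so the zero-anchor probability (~5·10⁻⁵) and the
chance-proximity background (< 1%) are both inside the binomial error
budget.

**Survival layer.** Event times are exponential with hazard
h₀·exp(Σβ·x); covariates are explicit per-patient features, z-scored true
intensities (`density:<panel>:<archetype>:<compartment>`), or Bernoulli(½)
arms. Censoring is independent uniform over [0, horizon], Bernoulli-thinned
to the requested rate — independence of the censoring time from the event
time is what preserves the proportional-hazards structure (an earlier
draft that censored at U(0, T] of the patient's own event time biased Cox
estimates detectably and is the reason this is spelled out here).
Administrative censoring applies at the horizon.

**Reproducibility.** One integer seed drives a cohort; per-field seeds are
derived through `SeedSequence` spawn keys (patient, panel, field index), so
any field can be regenerated in isolation and cohorts are byte-identical
across runs.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: no pixels or spectra (segmentation and unmixing
errors are out of scope), no staining noise by default (an optional marker
misclassification rate exists, default 0), no spatial inhomogeneity beyond
the nest geometry (no gradients, no exclusion zones, no cell-size
constraints), no inter-field correlation within a patient beyond shared
intensities, and no spatially varying hazard. Results on synthetic cohorts
validate the *estimators*, not the biology.

## Problem sizes

The default preset (21 patients × 2 panels × 20 fields, ~500 cells/field)
runs the full pipeline in a few seconds. Recovery analyses use 20
fields/patient for densities and fractions and 400 patients (1 minimal
field each) for Cox parameter recovery; type-I calibration uses 300 null
replicates of 60 patients. These sizes put Monte-Carlo error well inside
each test's stated band while keeping the whole suite fast.

## Known limitations

- No edge-effect correction in proximity metrics (documented bias).
- Percentage denominators are a convention; comparisons across studies
  using "all nucleated cells" denominators require re-configuration.
- The Immunoscore variant is median-based and cohort-relative: classes are
  not transferable across cohorts without refitting the medians.
- Univariate survival analysis only: no multivariable Cox, no
  proportionality diagnostics, no competing risks.
- Ingest mode expects binary marker calls; intensity thresholding belongs
  to the upstream segmentation/phenotyping software.
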