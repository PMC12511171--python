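# Methods

## Setting and data model

A slide carries classified cell centroids in micrometer coordinates (y
increasing downward, image convention; only relative distances enter any
statistic, so orientation and origin are inert) and up to three labeled
regions of interest — tumor core, transition zone, periphery — drawn as
polygons, with additional exclusion polygons for bleeding, necrosis,
tissue folds, and background staining. Exclusions are removed from both
numerators (cells inside them are dropped everywhere) and denominators
(areas are net of exclusions intersected with the region), on the view
that excluded tissue is unreliably stained rather than empty.

Polygons are closed: a point exactly on an edge belongs to the region.
Regions must be pairwise non-overlapping (validated with a 10⁻⁹ relative
area tolerance), so assignment is unambiguous except on shared boundaries,
a measure-zero set resolved deterministically by the fixed label order
core, transition, periphery. Every cell receives exactly one of
{CORE, TRANSITION, PERIPHERY, NONE, EXCLUDED}.

The quantitative core criterion — more than 60% of all cells (unstained
included) P53-positive — is implemented as an advisory tile-grid tool
(`tumor_fraction_grid` / `suggest_core_mask`, strict inequality, tiles
with fewer than `min_cells` = 20 cells undefined rather than zero to avoid
noise in sparse tiles). Analyses always use the supplied ROIs; the mask
only suggests, mirroring pathologist-approved region selection.

## Densities, ratios, waterfalls

Density is count over net region area (cells/mm²; 1 mm² = 10⁶ μm²), with
zero-count rows materialized for every present region × class so
downstream joins never silently drop strata. Ratios (IBA1/tumor,
CD8/tumor, FOXP3/tumor, FOXP3/CD8) are computed per patient and region —
the shared area cancels, so they equal count ratios exactly — and
summarized as cohort medians of per-patient ratios, which is not the ratio
of cohort medians and can differ from it substantially for skewed
features. A zero denominator count yields a missing value, never an
infinity, and missing values are excluded pairwise from cohort tests.
Unstained cells are carried in the density table (they anchor the tumor
fraction and total cellularity) but enter no ratio or figure. Waterfall
tables give per-patient signed density differences for the three region
contrasts, restricted to patients having both regions.

## Proximity statistic

For each reference (tumor) cell, the number of neighbor-class cells within
r = 30 μm is counted — Euclidean, center-to-center, boundary-inclusive
(d ≤ r), the simplest defensible reading of a fixed-radius rule; boundary
ties have measure zero for continuous coordinates. Counts are binned
0 / 1–4 / 5–9 / ≥10; the zero bin is tracked explicitly so per-region
fractions form a proper distribution (they sum to 1), although reports
typically show the three positive bins. Fractions are over the reference
cells of the region; the density variant divides bin counts by region area
instead, removing the dependence on total tumor-cell numbers.

Neighbors are searched over all non-excluded cells on the slide regardless
of region: cells do not respect ROI lines, and clipping at boundaries
would bias narrow regions. The reference cell's own region determines
attribution. No edge correction is applied at outer tissue boundaries —
naive counting, as commercial counting tools report — giving a small
downward bias for references within r of a boundary; on a 22 mm² test
slide the resulting mean absolute deviation from the analytic null is
≈ 0.005, an order of magnitude inside the 0.02 testing tolerance.

Counting uses a k-d tree (`scipy.spatial.cKDTree`); an O(n²) exhaustive
counter with the identical contract serves as the testing oracle, and the
closed-form Poisson null P(bin [a,b]) = Σ e^{−μ}μᵏ/k!, μ = λπr²·10⁻⁶,
provides the calibration reference for homogeneous independent classes.

## Cohort inference

Region contrasts use the paired two-sided Wilcoxon signed-rank test with
the classical conventions: zero differences dropped, average ranks for
tied magnitudes, exact enumeration p for n ≤ 25 without ties, otherwise
the tie-corrected, continuity-corrected normal approximation (delegated to
`scipy.stats.wilcoxon`; an independent 2ⁿ enumeration oracle checks
exactness in the tests). The reported W is the positive-rank sum.

The survival screen dichotomizes each per-patient feature at the cohort
median — high ⇔ strictly above, ties to low, a deterministic common
convention — and fits a univariate Cox proportional-hazards model (via
lifelines, Efron handling of tied event times, appropriate for
month-resolution data; Wald CI and p). "Univariate analyses with a
pre-specified median cutoff reporting an HR" pins down this model up to
the tie method. Non-convergence (e.g. complete separation with all events
in one group, or |log HR| > 15) is reported as an explicit flag, never a
number. P-values are raw by design; Benjamini–Hochberg is available behind
a flag. Degenerate features are skipped with a warning rather than
failing the screen.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
desk scale, so that pipeline properties are testable without slides:

- **Geometry** — concentric square bands with exactly the configured net
  areas, default 4 mm² per region. Published whole-region outlines span
  millimeter scales, and 4 mm² is the smallest round area at which the
  sparsest class (FOXP3, ~0.1–1.7 cells/mm²) yields enough counts for a
  cohort median to resolve the published core/transition gap rather than
  collapse onto the count grid.
- **Intensities** — per class and patient, log-normal with log-median at
  the published cohort medians, log-scale σ = 0.6 and exchangeable
  cross-region correlation ρ = 0.5 (z = √ρ·shared + √(1−ρ)·own). These two
  are calibration choices (the study reports medians, not dispersions):
  they reproduce mostly-positive waterfalls with a visible minority
  (~10–15%) of sign flips. Unstained-cell medians (800/1800/2800
  cells/mm², rising outward as normal brain takes over) are likewise a
  calibration choice, set so the median core tumor fraction sits just
  above the 60% criterion and total cellularity stays in a realistic
  3200–4000 cells/mm² band.
- **Point patterns** — homogeneous Poisson per class (count ~
  Poisson(λ·|R|), positions uniform by rejection sampling). Optional
  tumor-anchored immune recruitment: a configured fraction of an immune
  class's points become offspring of sampled tumor-cell parents with
  isotropic Gaussian displacement (default σ = 12 μm), total intensity
  preserved. Parents are *distinct* tumor cells and cluster sizes are
  fixed at ≈ `offspring_mean` (default 1) rather than Poisson-distributed:
  spreading the recruited mass over many parents is what raises the 30 μm
  co-occurrence fraction above the independence null. Few large clusters
  do the opposite — clumping shrinks the covered area faster than
  anchoring raises co-occurrence (measured excess ≈ −0.07 at cluster mean
  3 versus ≈ +0.03 at mean 1) — a property worth remembering when
  interpreting proximity fractions as "interaction". Clustering is off by
  default so null proximity fractions match the Poisson oracle.
- **Survival** — exponential death times with cohort median 14 months;
  progression as an independent competing exponential calibrated so the
  marginal PFS median is 7.6 months, sharing the covariate effect, which
  guarantees PFS ≤ OS. The binary covariate (high latent core tumor
  intensity) acts on both hazards with log-HR ln 0.46, centered (x − ½) so
  the configured medians are cohort-level. Censoring is administrative:
  per-patient uniform follow-up horizons of 57–234 months, a 15-year
  accrual window closed about five years after last inclusion, which
  reproduces a ~4% alive-at-censoring fraction.
- **Reproducibility** — one master seed; per-patient substreams spawned
  from it, so cohorts are bit-reproducible and patients regenerable
  independently. A truth record carries the latent intensity matrices,
  covariate, and true log-HR for recovery tests. A count-level fast path
  (`sample_density_cohort`) draws densities without placing points —
  distributionally identical to running the spatial pipeline with no
  exclusions — for many-seed calibration studies.

What the generator does **not** emulate: within-region intensity gradients
(each region is internally homogeneous), cell-size/segmentation effects
(cells are points), necrosis geometry, spatial correlation between immune
classes, and any dependence of survival on features other than the single
built-in covariate. Passing tests therefore demonstrate correctness of the
measurement and inference machinery under the assumed structure, not
biological validity on real slides.

## Numerical and design choices

- CSV dialect: comma, UTF-8, required header, "." decimal; configurable
  missing-value token (default empty string, "NA" accepted via config).
  Coordinates round-trip as full-precision decimal text.
- Reporting precision for the cohort summary mirrors mixed clinical-table
  conventions (one decimal for small percentages, integer otherwise),
  configurable. A cohort with no females reports an undefined sex ratio
  rather than dividing by zero.
- Outputs are tidy CSVs with stable column order plus a JSON run summary
  (seed, version, semantic-config hash — filesystem paths excluded so the
  hash is location-independent, and no timestamps, so identical inputs
  give byte-identical output trees).
- Region-ordering checks on ratio medians compare core against periphery;
  the periphery-versus-core increase is the robustly separated claim for
  both IBA1/tumor and CD8/tumor (≈ 0.7 natural-log units), whereas the
  transition-zone step for CD8/tumor (≈ 0.3) is within cohort-median noise
  at n = 54 under the default heterogeneity.

## Problem sizes used by the test suite

Unit tests run on toy slides and 8-patient cohorts at 0.5 mm² regions. The
validation suite uses: 100 random slides of ≤ 2000 cells for the
neighbor-count oracle; one 22 mm² homogeneous slide (~5×10⁴ reference
cells) for the Poisson null; all 2ⁿ sign patterns up to n = 12 for
Wilcoxon exactness; 500 count-level cohorts for the type-I rate; 200
replicates at n = 216 for Cox recovery; and 20 full default cohorts
(~2×10⁶ cells each) for ordering reproduction. The full suite runs in a
few minutes on one core.

## Known limitations

- The ordering-reproduction property is intentionally marginal: at n = 54
  with σ = 0.6, ρ = 0.5 the cohort-median log-SE (~0.10) is about half the
  smallest published separation (IBA1 core vs transition, 0.20), so the
  complete joint ordering holds in ~94% of cohorts, not all — the same
  heterogeneity that produces realistic waterfall sign flips occasionally
  flips the tightest median pair. Stabilizing it would require weaker
  heterogeneity than the waterfalls warrant.
- No edge correction in the proximity statistic (documented bias above).
- The survival screen is univariate by design; no multivariable
  adjustment, time-varying effects, or competing-risks handling.
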