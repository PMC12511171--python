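# gliospatial

Spatial quantification of tumor and immune cells across the three
histological zones of glioblastoma, IDH-wildtype: the densely tumorous
**core**, the infiltrating **transition zone**, and the **periphery** where
single tumor cells invade near-normal brain. The package is aimed at
digital-pathology and neuro-oncology groups who export classified cell
coordinates (e.g. from a multiplex-IHC deep-learning classifier) and region
annotations, and want the full downstream analysis: per-region densities,
immune-to-tumor ratios, fixed-radius proximity statistics, paired cohort
inference, and a median-cutoff survival screen — plus a calibrated
synthetic-cohort generator so every stage is testable without patient
slides.

## What it computes

Inputs are per-slide cell tables (`cell_id, x_um, y_um, cell_class` with
classes P53+ **TUMOR**, **IBA1**+ microglia/macrophages, **CD8**+ cytotoxic
T cells, **FOXP3**+ regulatory T cells, **UNSTAINED**), GeoJSON region
polygons (`CORE`/`TRANSITION`/`PERIPHERY` plus `EXCLUDE` artifact zones),
and a clinical table (OS/PFS in months with event flags).

- **Densities** — for region *R* with net area |R| (exclusions subtracted,
  mm²) and class *c*: λ̂\_c(R) = N\_c(R) / |R| in cells/mm².
- **Ratios** — per patient and region: IBA1/tumor, CD8/tumor, FOXP3/tumor,
  and the immunosuppression index FOXP3⁺/CD8⁺; cohort summaries are medians
  of per-patient ratios, never ratios of medians.
- **Waterfalls** — per-patient signed density differences between region
  pairs (core − periphery, transition − periphery, core − transition),
  exposing interpatient heterogeneity.
- **Proximity** — for every reference tumor cell, the number of immune
  cells of a class within r = 30 μm (Euclidean, center-to-center,
  boundary-inclusive), binned into 0 / 1–4 / 5–9 / ≥10; reported per region
  as the fraction of tumor cells per bin and as the un-normalized per-area
  density. The homogeneous-Poisson null for the bin [a, b] is
  Σ\_{k=a..b} e^{−μ} μᵏ/k! with μ = λπr²·10⁻⁶, available as an analytic
  oracle.
- **Inference** — paired two-sided Wilcoxon signed-rank contrasts between
  regions (exact for n ≤ 25 without ties); for each per-patient feature, a
  median split (high ⇔ value > cohort median) followed by a univariate Cox
  proportional-hazards fit (Efron ties, Wald 95% CI) against OS and PFS,
  with raw p-values.
- **Synthetic cohorts** — 54 patients by default; per-class, per-region
  log-normal intensities calibrated to the published cohort medians (tumor
  2301/1141/250, IBA1 512/419/179, CD8 14/10/3, FOXP3 1.7/1.2/0.1
  cells/mm²), homogeneous Poisson point patterns in concentric region
  bands, optional Thomas-style immune recruitment around tumor cells, and
  exponential OS/PFS with administrative censoring.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (shared default seed 42). `python analysis/01_simulate_cohort.py`
writes the cohort and prints its clinical summary next to the published
characteristics it emulates; `python analysis/02_quantify_densities.py`
then prints:

```
cohort median densities (cells/mm²):
cell_class region_label  median_density
     TUMOR         CORE        2262.250
     TUMOR   TRANSITION        1144.250
     TUMOR    PERIPHERY         295.250
      IBA1         CORE         556.875
      IBA1   TRANSITION         515.500
      IBA1    PERIPHERY         166.750
       CD8         CORE          12.375
       CD8   TRANSITION          11.000
       CD8    PERIPHERY           2.750
     FOXP3         CORE           1.625
     FOXP3   TRANSITION           1.000
     FOXP3    PERIPHERY           0.000
...
fraction of negative waterfall differences (sign flips): 0.12
```

i.e. the pipeline recovers the calibrated decrease of every cell class from
core to periphery on the published scale, while ~12% of per-patient
differences flip sign — the interpatient heterogeneity the generator is
built to reproduce. `analysis/03_proximity_analysis.py` compares observed
tumor-core proximity fractions with the Poisson null (they agree when
clustering is off), and `analysis/04_statistics_and_survival.py` prints the
significant region contrasts and the survival screen, which recovers the
one signal built into the generator: high core tumor density protective for
OS (true HR 0.46; one fitted run printed HR 0.32, 95% CI 0.17–0.60).

The same stages are available as a CLI
(`gliospatial simulate | quantify | proximity | stats | report`) with
`--config`, `--seed`, `--outdir`, `--radius`, `--force`, `--log-level`.

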