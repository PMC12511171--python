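"""End-to-end orchestration of the analysis.

Four stages, each runnable on its own (results land as tidy CSV plus a JSON
run summary): ``simulate`` writes a synthetic cohort in the pipeline's own
input formats; ``quantify`` reads cell tables and region GeoJSON and builds
density/ratio/waterfall tables; ``proximity`` builds the 30 μm neighbor
statistic; ``stats`` runs the paired region contrasts and the median-cutoff
survival screen.  Fixed seed and config give a byte-identical output tree.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .density import (
    CONTRASTS,
    RATIO_NAMES,
    build_density_table,
    build_ratio_table,
    build_waterfall_table,
    cohort_median_table,
)
from .inference import compare_regions, run_survival_screen
from .io import ANALYZED_CLASSES, REGION_LABELS
from .proximity import ProximityConfig, build_proximity_table
from .regions import assign_cells_to_regions
from .synthetic import SyntheticCohortConfig, generate_cohort

logger = logging.getLogger("gliospatial")

__all__ = [
    "PipelineConfig",
    "run_simulate",
    "run_quantify",
    "run_proximity",
    "run_stats",
    "load_config",
]


@dataclass
class PipelineConfig:
    outdir: Path = Path("results")
    seed: int = 0
    synthetic: SyntheticCohortConfig | None = None  # None: read real inputs
    cells_dir: Path | None = None  # real-input mode: per-patient CSV/GeoJSON
    clinical_path: Path | None = None
    proximity: ProximityConfig = field(default_factory=ProximityConfig)
    alpha: float = 0.05
    adjust_pvalues: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        real = self.cells_dir is not None
        if self.synthetic is not None and real:
            raise ValueError("configure either synthetic generation or real inputs, not both")

    def to_dict(self) -> dict:
        """Semantic configuration only: filesystem paths are excluded so the
        recorded config hash is stable across output locations."""
        d = dataclasses.asdict(self)
        for key in ("outdir", "cells_dir", "clinical_path"):
            d.pop(key, None)
        return d


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (missing keys take defaults)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in ("outdir", "seed", "alpha", "adjust_pvalues", "log_level",
                "cells_dir", "clinical_path"):
        if key in raw:
            kwargs[key] = raw[key]
    if "proximity" in raw:
        prox = dict(raw["proximity"])
        if "bins" in prox:
            prox["bins"] = tuple(
                (int(lo), None if hi in (None, "inf") else int(hi))
                for lo, hi in prox["bins"]
            )
        if "neighbor_classes" in prox:
            prox["neighbor_classes"] = tuple(prox["neighbor_classes"])
        kwargs["proximity"] = ProximityConfig(**prox)
    if "synthetic" in raw:
        synth = dict(raw["synthetic"])
        if "medians" in synth:
            synth["medians"] = {k: tuple(v) for k, v in synth["medians"].items()}
        if "region_areas" in synth:
            synth["region_areas"] = tuple(synth["region_areas"])
        kwargs["synthetic"] = SyntheticCohortConfig(**synth)
    return PipelineConfig(**kwargs)


def _cohort_dir(config: PipelineConfig) -> Path:
    return config.outdir / "cohort"


def run_simulate(config: PipelineConfig, force: bool = False) -> Path:
    """Generate the synthetic cohort and write it in the pipeline input formats."""
    synth = config.synthetic or SyntheticCohortConfig(seed=config.seed)
    if synth.seed != config.seed:
        synth = dataclasses.replace(synth, seed=config.seed)
    out = _cohort_dir(config)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True/--force to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(synth)
    for pid, cell_map in cohort.cell_maps.items():
        gio.write_cell_table(cell_map, out / f"{pid}_cells.csv")
        gio.write_region_annotations(cohort.region_sets[pid], out / f"{pid}_regions.geojson")
    gio.write_clinical_table(cohort.clinical, out / "clinical.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
    n_cells = sum(m.n_cells for m in cohort.cell_maps.values())
    logger.info("wrote %d patients, %d cells to %s", synth.n_patients, n_cells, out)
    return out


def _load_cohort_inputs(config: PipelineConfig):
    """Read per-patient cell tables and region annotations from disk."""
    cells_dir = config.cells_dir or _cohort_dir(config)
    cells_dir = Path(cells_dir)
    cell_paths = sorted(cells_dir.glob("*_cells.csv"))
    if not cell_paths:
        raise FileNotFoundError(f"no *_cells.csv files under {cells_dir}")
    cohort = {}
    for path in cell_paths:
        pid = path.name.removesuffix("_cells.csv")
        region_path = cells_dir / f"{pid}_regions.geojson"
        if not region_path.exists():
            raise FileNotFoundError(f"missing region annotations {region_path}")
        cohort[pid] = (
            gio.read_cell_table(path, patient_id=pid),
            gio.read_region_annotations(region_path, patient_id=pid),
        )
    return cohort


def _load_clinical(config: PipelineConfig):
    path = config.clinical_path or _cohort_dir(config) / "clinical.csv"
    return gio.read_clinical_table(path)


def run_quantify(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Assign cells to regions and build density, ratio, and waterfall tables."""
    cohort = _load_cohort_inputs(config)
    density_parts = []
    for pid, (cell_map, region_set) in cohort.items():
        labeled = assign_cells_to_regions(cell_map, region_set)
        density_parts.append(build_density_table(labeled, region_set))
    density = pd.concat(density_parts, ignore_index=True)
    tables = {
        "density": density,
        "ratios": build_ratio_table(density),
        "waterfall": build_waterfall_table(density),
        "cohort_medians": cohort_median_table(density),
    }
    gio.write_results(
        tables, config.outdir / "tables", seed=config.seed, config=config.to_dict()
    )
    medians = tables["cohort_medians"]
    for cls in ANALYZED_CLASSES:
        row = medians[medians["cell_class"] == cls]
        logger.info(
            "cohort median %s density (cells/mm², core/tz/periphery): %s",
            cls,
            ", ".join(
                f"{row[row['region_label'] == r]['median_density'].squeeze():.3g}"
                for r in REGION_LABELS
                if (row["region_label"] == r).any()
            ),
        )
    return tables


def run_proximity(config: PipelineConfig) -> pd.DataFrame:
    """Build the fixed-radius proximity table for every patient."""
    cohort = _load_cohort_inputs(config)
    parts = []
    for pid, (cell_map, region_set) in cohort.items():
        labeled = assign_cells_to_regions(cell_map, region_set)
        parts.append(build_proximity_table(labeled, region_set, config.proximity))
    table = pd.concat(parts, ignore_index=True)
    gio.write_results(
        {"proximity": table}, config.outdir / "tables",
        seed=config.seed, config=config.to_dict(),
    )
    return table


_REGION_PAIRS = (("CORE", "PERIPHERY"), ("TRANSITION", "PERIPHERY"), ("CORE", "TRANSITION"))


def run_stats(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Paired region comparisons and the median-cutoff survival screen.

    Requires the quantify (and, for proximity metrics, proximity) outputs
    under ``<outdir>/tables``.  Metrics that cannot be tested (degenerate or
    too few pairs) are logged and skipped, not fatal.
    """
    tables_dir = config.outdir / "tables"
    density = pd.read_csv(tables_dir / "density.csv")
    ratios = pd.read_csv(tables_dir / "ratios.csv")
    prox_path = tables_dir / "proximity.csv"
    proximity = pd.read_csv(prox_path) if prox_path.exists() else None

    comparisons = []

    def _compare(df, metric_name, value_col):
        for pair in _REGION_PAIRS:
            try:
                c = compare_regions(df, metric_name, pair, value_col=value_col)
            except ValueError as exc:
                logger.warning("skipping %s %s: %s", metric_name, pair, exc)
                continue
            logger.info("%s %s vs %s: n_pairs=%d p=%.4g",
                        metric_name, pair[0], pair[1], c.n_pairs, c.p_value)
            comparisons.append(
                {
                    "metric": c.metric_name,
                    "region_a": c.region_pair[0],
                    "region_b": c.region_pair[1],
                    "n_pairs": c.n_pairs,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "median_a": c.median_a,
                    "median_b": c.median_b,
                }
            )

    for cls in ANALYZED_CLASSES:
        sub = density[density["cell_class"] == cls]
        _compare(sub, f"density_{cls}", "density")
    for name, _, _ in RATIO_NAMES:
        sub = ratios[ratios["ratio_name"] == name]
        _compare(sub, f"ratio_{name}", "value")
    if proximity is not None:
        for ncls in sorted(proximity["neighbor_class"].unique()):
            for bin_label in sorted(proximity["bin_label"].unique()):
                if bin_label == "b0":
                    continue
                sub = proximity[
                    (proximity["neighbor_class"] == ncls)
                    & (proximity["bin_label"] == bin_label)
                ]
                _compare(sub, f"proximity_{ncls}_{bin_label}_fraction", "fraction")
    comparisons = pd.DataFrame(comparisons)

    # per-patient feature matrix for the survival screen
    features = {}
    dens_wide = density.pivot_table(
        index="patient_id", columns=["cell_class", "region_label"], values="density"
    )
    for (cls, region) in dens_wide.columns:
        if cls in ANALYZED_CLASSES:
            features[f"density_{cls}_{region}"] = dens_wide[(cls, region)]
    if proximity is not None:
        prox_wide = proximity[proximity["bin_label"] != "b0"].pivot_table(
            index="patient_id",
            columns=["neighbor_class", "bin_label", "region_label"],
            values="density",
        )
        for col in prox_wide.columns:
            features["proximity_density_" + "_".join(col)] = prox_wide[col]
    features = pd.DataFrame(features)

    clinical = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "os_months": r.os_months,
                "os_event": r.os_event,
                "pfs_months": r.pfs_months,
                "pfs_event": r.pfs_event,
            }
            for r in _load_clinical(config)
        ]
    )
    missing = set(features.index) - set(clinical["patient_id"])
    if missing:
        logger.warning("patients without clinical records: %s", sorted(missing))
    screen = run_survival_screen(features, clinical, adjust=config.adjust_pvalues)

    out = {"comparisons": comparisons, "survival_screen": screen}
    gio.write_results(out, config.outdir / "tables",
                      seed=config.seed, config=config.to_dict())
    return out
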