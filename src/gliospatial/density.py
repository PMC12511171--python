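"""Per-region, per-class cell counts, densities, ratios, and waterfalls.

All tables are tidy pandas DataFrames so they can be written directly as
CSV and fed to the cohort statistics.  Densities are cells per mm² over the
net (exclusion-subtracted) region area.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ANALYZED_CLASSES, CELL_CLASSES, REGION_LABELS
from .regions import RegionSet

__all__ = [
    "cell_density",
    "build_density_table",
    "build_ratio_table",
    "build_waterfall_table",
    "RATIO_NAMES",
    "CONTRASTS",
    "cohort_median_table",
]

DENSITY_COLUMNS = ["patient_id", "region_label", "cell_class", "count", "area_mm2", "density"]

#: immune-to-tumor ratios plus the FOXP3/CD8 immunosuppression index,
#: each as (name, numerator class, denominator class)
RATIO_NAMES: tuple[tuple[str, str, str], ...] = (
    ("IBA1_per_tumor", "IBA1", "TUMOR"),
    ("CD8_per_tumor", "CD8", "TUMOR"),
    ("FOXP3_per_tumor", "FOXP3", "TUMOR"),
    ("FOXP3_per_CD8", "FOXP3", "CD8"),
)

#: waterfall contrasts as (name, first region, second region)
CONTRASTS: tuple[tuple[str, str, str], ...] = (
    ("core_minus_periphery", "CORE", "PERIPHERY"),
    ("tz_minus_periphery", "TRANSITION", "PERIPHERY"),
    ("core_minus_tz", "CORE", "TRANSITION"),
)


def cell_density(count: float, area_mm2: float) -> float:
    """Cells per mm² from a count and a net region area."""
    if count < 0:
        raise ValueError("count must be nonnegative")
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    return count / area_mm2


def build_density_table(labeled_cells: pd.DataFrame, region_set: RegionSet) -> pd.DataFrame:
    """Counts and densities per (patient, region, class) for one slide.

    ``labeled_cells`` is the output of :func:`assign_cells_to_regions`.
    Every present region gets a row for each of the five classes (zero
    counts included); EXCLUDED cells are never counted.
    """
    areas = region_set.areas()
    counted = labeled_cells[labeled_cells["region"].isin(region_set.labels)]
    counts = counted.groupby(["region", "cell_class"]).size().to_dict()
    patient_id = labeled_cells["patient_id"].iloc[0]
    rows = []
    for label in region_set.labels:
        area = areas[label]
        for cls in CELL_CLASSES:
            n = int(counts.get((label, cls), 0))
            rows.append(
                {
                    "patient_id": patient_id,
                    "region_label": label,
                    "cell_class": cls,
                    "count": n,
                    "area_mm2": area,
                    "density": cell_density(n, area),
                }
            )
    return pd.DataFrame(rows, columns=DENSITY_COLUMNS)


def build_ratio_table(density_table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient, per-region immune/tumor and FOXP3/CD8 density ratios.

    Ratios are computed within a (patient, region), so the shared area
    cancels and the value equals the count ratio.  A zero denominator count
    yields a missing (NaN) value, never an infinity; UNSTAINED cells take no
    part in any ratio.
    """
    wide_count = density_table.pivot_table(
        index=["patient_id", "region_label"],
        columns="cell_class",
        values="count",
        aggfunc="first",
    )
    wide_density = density_table.pivot_table(
        index=["patient_id", "region_label"],
        columns="cell_class",
        values="density",
        aggfunc="first",
    )
    rows = []
    for (patient, region), dens in wide_density.iterrows():
        cnt = wide_count.loc[(patient, region)]
        for name, num, den in RATIO_NAMES:
            if cnt.get(den, 0) == 0 or np.isnan(cnt.get(den, np.nan)):
                value = np.nan
            else:
                value = dens[num] / dens[den]
            rows.append(
                {
                    "patient_id": patient,
                    "region_label": region,
                    "ratio_name": name,
                    "value": value,
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "region_label", "ratio_name", "value"])


def build_waterfall_table(density_table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient signed density differences between region pairs.

    One row per patient × analyzed class × contrast where the patient has
    both regions; patients missing a region are omitted from that contrast.
    """
    wide = density_table[density_table["cell_class"].isin(ANALYZED_CLASSES)].pivot_table(
        index=["patient_id", "cell_class"],
        columns="region_label",
        values="density",
        aggfunc="first",
    )
    rows = []
    for (patient, cls), dens in wide.iterrows():
        for name, first, second in CONTRASTS:
            if first in dens.index and second in dens.index:
                a, b = dens[first], dens[second]
                if np.isnan(a) or np.isnan(b):
                    continue
                rows.append(
                    {
                        "patient_id": patient,
                        "cell_class": cls,
                        "contrast": name,
                        "difference": a - b,
                    }
                )
    return pd.DataFrame(rows, columns=["patient_id", "cell_class", "contrast", "difference"])


def cohort_median_table(density_table: pd.DataFrame) -> pd.DataFrame:
    """Cohort median density per (region, class) — the headline figure numbers."""
    med = (
        density_table.groupby(["cell_class", "region_label"])["density"]
        .median()
        .rename("median_density")
        .reset_index()
    )
    order = {c: i for i, c in enumerate(CELL_CLASSES)}
    rorder = {r: i for i, r in enumerate(REGION_LABELS)}
    med = med.sort_values(
        by=["cell_class", "region_label"],
        key=lambda s: s.map(order if s.name == "cell_class" else rorder),
    ).reset_index(drop=True)
    return med
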