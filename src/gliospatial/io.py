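"""Reading and writing of the pipeline's external formats.

Cell tables and clinical tables are plain CSV (comma-separated, UTF-8,
header row, ``.`` decimal separator — the dialect common pathology export
tools can be configured to emit); region annotations are GeoJSON
FeatureCollections with polygon coordinates in micrometers.  Coordinates
are slide coordinates with y increasing downward (image convention); only
relative distances are ever used, so orientation is inert.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import shapely.geometry

__all__ = [
    "CELL_CLASSES",
    "IMMUNE_CLASSES",
    "ANALYZED_CLASSES",
    "REGION_LABELS",
    "FormatError",
    "SlideCellMap",
    "ClinicalRecord",
    "CohortSummary",
    "read_cell_table",
    "write_cell_table",
    "read_region_annotations",
    "write_region_annotations",
    "read_clinical_table",
    "write_clinical_table",
    "summarize_cohort",
    "write_results",
    "config_hash",
]

#: Classifier output classes: P53+ tumor cells, IBA1+ microglia/macrophages,
#: CD8+ cytotoxic T cells, FOXP3+ regulatory T cells, and unstained cells.
CELL_CLASSES: tuple[str, ...] = ("TUMOR", "IBA1", "CD8", "FOXP3", "UNSTAINED")
IMMUNE_CLASSES: tuple[str, ...] = ("IBA1", "CD8", "FOXP3")
#: Classes carried into figures/ratios (UNSTAINED is counted but not analyzed).
ANALYZED_CLASSES: tuple[str, ...] = ("TUMOR", "IBA1", "CD8", "FOXP3")
#: Region-of-interest labels, ordered from tumor center outward.
REGION_LABELS: tuple[str, ...] = ("CORE", "TRANSITION", "PERIPHERY")

_CELL_COLUMNS = ("cell_id", "x_um", "y_um", "cell_class")


class FormatError(ValueError):
    """An input file violates the expected structure or vocabulary."""


@dataclass
class SlideCellMap:
    """Classified cell coordinates for one patient slide.

    ``cells`` is a DataFrame with columns ``cell_id, x, y, cell_class``;
    coordinates are micrometers in slide space.
    """

    patient_id: str
    cells: pd.DataFrame
    units: str = "micrometers"

    def __post_init__(self) -> None:
        if len(self.cells) == 0:
            raise FormatError("a slide cell map must contain at least one cell")
        xy = self.cells[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise FormatError("cell coordinates must be finite")
        bad = set(self.cells["cell_class"].unique()) - set(CELL_CLASSES)
        if bad:
            raise FormatError(
                f"unknown cell class(es) {sorted(bad)}; allowed: {list(CELL_CLASSES)}"
            )
        if self.cells["cell_id"].duplicated().any():
            dup = self.cells["cell_id"][self.cells["cell_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate cell_id {dup!r} within slide")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def class_counts(self) -> pd.Series:
        return self.cells["cell_class"].value_counts()


def read_cell_table(source, patient_id: str | None = None) -> SlideCellMap:
    """Read a classified-cell CSV into a :class:`SlideCellMap`.

    The table must have (case-insensitive) columns ``cell_id, x_um, y_um,
    cell_class``; an optional ``patient_id`` column is honored when the
    ``patient_id`` argument is not given.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _CELL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"cell table is missing required column {col!r}")
    if patient_id is None:
        if "patient_id" in df.columns:
            ids = df["patient_id"].unique()
            if len(ids) != 1:
                raise FormatError("cell table mixes multiple patient_id values")
            patient_id = str(ids[0])
        elif isinstance(source, (str, Path)):
            patient_id = Path(source).stem
        else:
            patient_id = "slide"

    out = pd.DataFrame({"cell_id": df["cell_id"]})
    for col, name in (("x_um", "x"), ("y_um", "y")):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        if bad.any():
            # +2: one for the header, one for 1-based line numbers
            line = int(np.flatnonzero(bad)[0]) + 2
            raise FormatError(
                f"non-finite or non-numeric {col} at line {line}: "
                f"{df[col].iloc[int(np.flatnonzero(bad)[0])]!r}"
            )
        out[name] = vals.to_numpy(dtype=float)
    out["cell_class"] = df["cell_class"].str.strip().str.upper()
    return SlideCellMap(patient_id=patient_id, cells=out)


def write_cell_table(cell_map: SlideCellMap, path) -> None:
    """Write a cell map back to CSV at full coordinate precision."""
    df = pd.DataFrame(
        {
            "cell_id": cell_map.cells["cell_id"],
            "x_um": cell_map.cells["x"],
            "y_um": cell_map.cells["y"],
            "cell_class": cell_map.cells["cell_class"],
            "patient_id": cell_map.patient_id,
        }
    )
    df.to_csv(path, index=False)


# -- region annotations -------------------------------------------------------

_REGION_FEATURE_LABELS = REGION_LABELS + ("EXCLUDE",)


def read_region_annotations(source, patient_id: str | None = None):
    """Read ROI polygons from a GeoJSON FeatureCollection.

    Each feature carries a ``region_label`` property in
    ``{CORE, TRANSITION, PERIPHERY, EXCLUDE}`` and a Polygon/MultiPolygon
    geometry in micrometers.  EXCLUDE geometries (bleeding, necrosis, tissue
    folds, background staining) become slide-level exclusion zones attached
    to every region; several features with the same region label are unioned.
    """
    from .regions import Region, RegionSet  # local import to avoid a cycle

    if isinstance(source, (str, Path)):
        with open(source) as fh:
            gj = json.load(fh)
        if patient_id is None:
            patient_id = Path(source).stem.removesuffix("_regions")
    else:
        gj = json.load(source)
    if patient_id is None:
        patient_id = str(gj.get("patient_id", "slide"))
    if gj.get("type") != "FeatureCollection":
        raise FormatError("region annotations must be a GeoJSON FeatureCollection")

    geoms: dict[str, list] = {}
    exclusions: list = []
    for i, feat in enumerate(gj.get("features", [])):
        label = (feat.get("properties") or {}).get("region_label")
        if label is None or str(label).upper() not in _REGION_FEATURE_LABELS:
            raise FormatError(
                f"feature {i}: unknown region_label {label!r}; "
                f"allowed: {list(_REGION_FEATURE_LABELS)}"
            )
        label = str(label).upper()
        geom = shapely.geometry.shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise FormatError(f"feature {i}: geometry must be Polygon/MultiPolygon")
        if not geom.is_valid or geom.area <= 0:
            raise FormatError(f"feature {i}: invalid or degenerate polygon")
        if label == "EXCLUDE":
            exclusions.append(geom)
        else:
            geoms.setdefault(label, []).append(geom)

    regions = {}
    for label, parts in geoms.items():
        geom = shapely.union_all(parts) if len(parts) > 1 else parts[0]
        regions[label] = Region(label=label, geometry=geom, exclusions=tuple(exclusions))
    return RegionSet(patient_id=patient_id, regions=regions)


def write_region_annotations(region_set, path) -> None:
    """Write a RegionSet to GeoJSON (regions plus slide-level exclusions)."""
    features = []
    exclusions_written = False
    for label in REGION_LABELS:
        region = region_set.regions.get(label)
        if region is None:
            continue
        features.append(
            {
                "type": "Feature",
                "properties": {"region_label": label},
                "geometry": shapely.geometry.mapping(region.geometry),
            }
        )
        if not exclusions_written:
            for excl in region.exclusions:
                features.append(
                    {
                        "type": "Feature",
                        "properties": {"region_label": "EXCLUDE"},
                        "geometry": shapely.geometry.mapping(excl),
                    }
                )
            exclusions_written = True
    gj = {
        "type": "FeatureCollection",
        "patient_id": region_set.patient_id,
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


# -- clinical table -----------------------------------------------------------

_ENUM_VOCAB: dict[str, tuple[str, ...]] = {
    "age_group": ("under65", "at_least65"),
    "sex": ("male", "female"),
    "performance_status": ("ps0_2", "gt2", "missing"),
    "treatment": ("rt_chemo", "palliative", "none"),
    "mgmt": ("methylated", "unmethylated", "unknown"),
    "surgery": ("biopsy", "partial", "total"),
    "midline": ("yes", "none", "missing"),
}
#: enum fields whose missing-token value maps to an explicit level
_MISSING_LEVEL = {"performance_status": "missing", "mgmt": "unknown", "midline": "missing"}
_TRUE_TOKENS = {"1", "true", "yes", "t", "y"}
_FALSE_TOKENS = {"0", "false", "no", "f", "n"}


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's outcome and covariate record.

    Survival is measured in months from initial surgery; ``os_event`` is
    death, ``pfs_event`` progression or death (censored otherwise).
    """

    patient_id: str
    os_months: float
    os_event: bool
    pfs_months: float
    pfs_event: bool
    age_group: str
    sex: str
    performance_status: str
    treatment: str
    mgmt: str
    surgery: str
    midline: str

    def __post_init__(self) -> None:
        if not (self.os_months > 0 and self.pfs_months > 0):
            raise FormatError(
                f"patient {self.patient_id}: survival months must be positive"
            )
        if self.pfs_months > self.os_months + 1e-9:
            raise FormatError(
                f"patient {self.patient_id}: pfs_months exceeds os_months"
            )
        for fieldname, vocab in _ENUM_VOCAB.items():
            value = getattr(self, fieldname)
            if value not in vocab:
                raise FormatError(
                    f"patient {self.patient_id}: {fieldname}={value!r} "
                    f"not in {list(vocab)}"
                )


def _parse_bool(token: str, row: int, col: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise FormatError(f"row {row}: cannot parse {col}={token!r} as a boolean")


def read_clinical_table(source, missing_token: str = "") -> list[ClinicalRecord]:
    """Read the per-patient clinical CSV into ClinicalRecords.

    Enum values are normalized to lowercase; the configurable missing-value
    token (default: empty string) maps performance status and midline to
    ``missing`` and MGMT to ``unknown``.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ("patient_id", "os_months", "os_event", "pfs_months", "pfs_event") + tuple(
        _ENUM_VOCAB
    )
    for col in required:
        if col not in df.columns:
            raise FormatError(f"clinical table is missing required column {col!r}")

    records: list[ClinicalRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        values: dict[str, object] = {"patient_id": str(row["patient_id"])}
        for col in ("os_months", "pfs_months"):
            try:
                months = float(row[col])
            except ValueError as exc:
                raise FormatError(f"row {i}: non-numeric {col}={row[col]!r}") from exc
            if months < 0:
                raise FormatError(f"row {i}: negative survival time {col}={months}")
            values[col] = months
        values["os_event"] = _parse_bool(row["os_event"], i, "os_event")
        values["pfs_event"] = _parse_bool(row["pfs_event"], i, "pfs_event")
        for fieldname, vocab in _ENUM_VOCAB.items():
            token = str(row[fieldname]).strip()
            if token == missing_token and fieldname in _MISSING_LEVEL:
                values[fieldname] = _MISSING_LEVEL[fieldname]
                continue
            norm = token.lower()
            if norm not in vocab:
                raise FormatError(
                    f"row {i}: {fieldname}={token!r} not in {list(vocab)}"
                )
            values[fieldname] = norm
        records.append(ClinicalRecord(**values))
    return records


def write_clinical_table(records: Sequence[ClinicalRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "os_months": r.os_months,
                "os_event": int(r.os_event),
                "pfs_months": r.pfs_months,
                "pfs_event": int(r.pfs_event),
                **{f: getattr(r, f) for f in _ENUM_VOCAB},
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)


# -- cohort summary -----------------------------------------------------------


@dataclass(frozen=True)
class CohortSummary:
    """Cohort characteristics analogous to a clinical baseline table."""

    n_patients: int
    n_alive: int
    pct_alive: float
    n_under65: int
    pct_under65: float
    male_to_female_ratio: float | None  # None when no females (undefined)
    n_rt_chemo: int
    pct_rt_chemo: float
    median_os: float
    os_range: tuple[float, float]
    median_pfs: float
    pfs_range: tuple[float, float]


def summarize_cohort(
    records: Sequence[ClinicalRecord],
    pct_alive_decimals: int = 1,
    pct_decimals: int = 0,
) -> CohortSummary:
    """Compute the cohort-characteristics summary.

    Reporting precision mirrors typical clinical baseline tables: small
    percentages (alive) at one decimal, the rest at integer percent, and the
    male-to-female ratio at one decimal; both precisions are configurable.
    A cohort with no females gets an undefined (None) ratio rather than a
    division error.
    """
    if len(records) == 0:
        raise ValueError("summarize_cohort requires at least one record")
    n = len(records)
    n_alive = sum(not r.os_event for r in records)
    n_under65 = sum(r.age_group == "under65" for r in records)
    n_male = sum(r.sex == "male" for r in records)
    n_female = n - n_male
    n_rt_chemo = sum(r.treatment == "rt_chemo" for r in records)
    os_months = np.array([r.os_months for r in records])
    pfs_months = np.array([r.pfs_months for r in records])
    return CohortSummary(
        n_patients=n,
        n_alive=n_alive,
        pct_alive=round(100.0 * n_alive / n, pct_alive_decimals),
        n_under65=n_under65,
        pct_under65=round(100.0 * n_under65 / n, pct_decimals),
        male_to_female_ratio=(round(n_male / n_female, 1) if n_female else None),
        n_rt_chemo=n_rt_chemo,
        pct_rt_chemo=round(100.0 * n_rt_chemo / n, pct_decimals),
        median_os=float(np.median(os_months)),
        os_range=(float(os_months.min()), float(os_months.max())),
        median_pfs=float(np.median(pfs_months)),
        pfs_range=(float(pfs_months.min()), float(pfs_months.max())),
    )


# -- tidy output writer -------------------------------------------------------


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    destination,
    seed: int | None = None,
    config: Mapping | None = None,
) -> dict:
    """Write tidy CSV tables plus a JSON run-metadata summary.

    Each table goes to ``<destination>/<name>.csv`` with its existing column
    order (builders emit a stable documented order); metadata (seed, package
    version, config hash, row counts) goes to ``<destination>/run_summary.json``.
    Output contains no timestamps, so re-running with identical inputs yields
    byte-identical files.
    """
    from . import __version__

    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    if not tables:
        raise ValueError("no tables to write")
    meta: dict = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "tables": {},
    }
    for name, df in tables.items():
        if len(df) == 0:
            raise ValueError(f"table {name!r} is empty; refusing to write")
        path = destination / f"{name}.csv"
        df.to_csv(path, index=False)
        meta["tables"][name] = {"rows": int(len(df)), "columns": list(df.columns)}
    with open(destination / "run_summary.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return meta
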