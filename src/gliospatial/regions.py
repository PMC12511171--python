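"""Geometry of labeled slide regions.

A slide carries up to three regions of interest — tumor core, transition
zone, and periphery — as polygons in micrometer coordinates, plus exclusion
polygons (bleeding, necrosis, folds, background staining) that are removed
from both cell counts and area denominators.  Boundary convention: polygons
are closed, so a point exactly on an edge belongs to the region; regions
must be pairwise non-overlapping, so the assignment is unambiguous up to a
measure-zero set of shared boundaries, resolved by the fixed label order
CORE, TRANSITION, PERIPHERY.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .io import FormatError, REGION_LABELS, SlideCellMap

__all__ = [
    "Region",
    "RegionSet",
    "TumorFractionGrid",
    "region_area",
    "assign_cells_to_regions",
    "tumor_fraction_grid",
    "suggest_core_mask",
    "UM2_PER_MM2",
]

UM2_PER_MM2 = 1.0e6
_REL_TOL = 1e-9


@dataclass
class Region:
    """One labeled ROI polygon with its exclusion zones (all in μm)."""

    label: str
    geometry: BaseGeometry
    exclusions: tuple[BaseGeometry, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise FormatError(f"unknown region label {self.label!r}")
        if not self.geometry.is_valid:
            raise FormatError(f"region {self.label}: invalid (self-intersecting?) polygon")
        if self.geometry.area <= 0:
            raise FormatError(f"region {self.label}: degenerate zero-area polygon")

    @property
    def effective_geometry(self) -> BaseGeometry:
        """Geometry minus exclusions (what counts and areas are taken over)."""
        if not self.exclusions:
            return self.geometry
        return self.geometry.difference(shapely.union_all(list(self.exclusions)))


def region_area(region: Region) -> float:
    """Net region area in mm²: polygon area minus overlapping exclusion area.

    Exclusions are intersected with the region first, so an exclusion lying
    outside the region has no effect.  1 mm² = 10⁶ μm².
    """
    area_um2 = region.geometry.area
    if region.exclusions:
        excl = shapely.union_all(list(region.exclusions))
        area_um2 -= region.geometry.intersection(excl).area
    area = area_um2 / UM2_PER_MM2
    if area <= 0:
        raise ValueError(f"region {region.label}: net area is not positive")
    return area


@dataclass
class RegionSet:
    """All labeled regions of one slide (at most one per label)."""

    patient_id: str
    regions: dict[str, Region]

    def __post_init__(self) -> None:
        if not self.regions:
            raise FormatError("a region set must contain at least one region")
        labels = list(self.regions)
        for label, region in self.regions.items():
            if region.label != label:
                raise FormatError("region dict key and region label disagree")
        # pairwise non-overlap (after exclusion subtraction); boundary contact ok
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                ga = self.regions[a].effective_geometry
                gb = self.regions[b].effective_geometry
                inter = ga.intersection(gb).area
                if inter > _REL_TOL * min(ga.area, gb.area):
                    raise FormatError(f"regions {a} and {b} overlap")

    @property
    def labels(self) -> list[str]:
        return [l for l in REGION_LABELS if l in self.regions]

    def areas(self) -> dict[str, float]:
        """Net areas in mm² keyed by region label."""
        return {label: region_area(r) for label, r in self.regions.items()}

    @property
    def exclusions(self) -> tuple[BaseGeometry, ...]:
        for region in self.regions.values():
            if region.exclusions:
                return region.exclusions
        return ()


def assign_cells_to_regions(cell_map: SlideCellMap, region_set: RegionSet) -> pd.DataFrame:
    """Label every cell with the region containing it.

    Returns a copy of the cell table with a ``region`` column taking values
    in {CORE, TRANSITION, PERIPHERY, NONE, EXCLUDED} plus ``patient_id``.
    Cells inside an exclusion polygon are EXCLUDED regardless of region and
    are dropped from every downstream count; cells outside all polygons are
    NONE.  Edge-inclusive containment (closed polygons).
    """
    cells = cell_map.cells.copy()
    x = cells["x"].to_numpy(dtype=float)
    y = cells["y"].to_numpy(dtype=float)
    region = np.full(len(cells), "NONE", dtype=object)

    unassigned = np.ones(len(cells), dtype=bool)
    for label in REGION_LABELS:
        if label not in region_set.regions:
            continue
        geom = region_set.regions[label].geometry
        shapely.prepare(geom)
        idx = np.flatnonzero(unassigned)
        if idx.size == 0:
            break
        # intersects == covers for points: boundary-inclusive
        hit = shapely.intersects_xy(geom, x[idx], y[idx])
        region[idx[hit]] = label
        unassigned[idx[hit]] = False

    for excl in region_set.exclusions:
        shapely.prepare(excl)
        hit = shapely.intersects_xy(excl, x, y)
        region[hit] = "EXCLUDED"

    cells["region"] = region
    cells.insert(0, "patient_id", cell_map.patient_id)
    return cells


@dataclass
class TumorFractionGrid:
    """Per-tile total/tumor counts and tumor fraction over the cell bounding box.

    ``fraction`` is NaN (undefined, not zero) for tiles with fewer than
    ``min_cells`` cells; the denominator is the total cell population of the
    tile, unstained cells included.
    """

    tile_size: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    total: np.ndarray
    tumor: np.ndarray
    min_cells: int

    @property
    def fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.tumor / self.total
        frac = np.where(self.total >= self.min_cells, frac, np.nan)
        return frac


def tumor_fraction_grid(
    cell_map: SlideCellMap, tile_size: float, min_cells: int = 20
) -> TumorFractionGrid:
    """Tile the slide and compute the tumor fraction per tile.

    Used as an advisory quantitative check of the core criterion (a core
    shows more than 60% tumor cells among all cells); analyses always use
    the supplied ROIs.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    cells = cell_map.cells
    x = cells["x"].to_numpy(dtype=float)
    y = cells["y"].to_numpy(dtype=float)
    nx = max(1, int(np.ceil((x.max() - x.min()) / tile_size)))
    ny = max(1, int(np.ceil((y.max() - y.min()) / tile_size)))
    x_edges = x.min() + tile_size * np.arange(nx + 1)
    y_edges = y.min() + tile_size * np.arange(ny + 1)
    total, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
    is_tumor = (cells["cell_class"] == "TUMOR").to_numpy()
    tumor, _, _ = np.histogram2d(x[is_tumor], y[is_tumor], bins=(x_edges, y_edges))
    return TumorFractionGrid(
        tile_size=tile_size,
        x_edges=x_edges,
        y_edges=y_edges,
        total=total,
        tumor=tumor,
        min_cells=min_cells,
    )


def suggest_core_mask(grid: TumorFractionGrid, threshold: float = 0.60) -> np.ndarray:
    """Tiles whose tumor fraction strictly exceeds the core threshold.

    Strict inequality implements the "over 60%" core criterion; undefined
    (sparse) tiles are never suggested.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    frac = grid.fraction
    return np.where(np.isnan(frac), False, frac > threshold)
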