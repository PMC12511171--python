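"""Fixed-radius neighbor statistics around reference tumor cells.

For every reference cell (tumor cells by default) the number of immune
cells of a given class within a 30 μm radius is counted, the counts are
binned (0, 1–4, 5–9, ≥10), and per region the fraction of reference cells
in each bin is reported alongside the un-normalized per-area density of
reference cells in each bin.

Distance is Euclidean, center-to-center, boundary-inclusive (≤ r).
Neighbors are counted across region boundaries — cells do not respect ROI
lines — while the reference cell's own region determines attribution.  No
edge correction is applied at tissue/ROI outer boundaries (naive counting,
matching what cell-counting software reports); the resulting small downward
bias is quantifiable against the Poisson null oracle.

The module also carries two testing oracles: a closed-form Poisson null
(:func:`poisson_bin_probability`) for slides where neighbor positions are
independent of references, and an O(n²) brute-force counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .io import IMMUNE_CLASSES
from .regions import RegionSet

__all__ = [
    "ProximityConfig",
    "count_neighbors_within",
    "brute_force_neighbor_counts",
    "bin_neighbor_counts",
    "build_proximity_table",
    "poisson_bin_probability",
]

DEFAULT_BINS: tuple[tuple[int, int | None], ...] = ((1, 4), (5, 9), (10, None))
PROXIMITY_COLUMNS = [
    "patient_id",
    "region_label",
    "neighbor_class",
    "bin_label",
    "n_reference_in_bin",
    "fraction",
    "density",
]


def _bin_label(lo: int, hi: int | None) -> str:
    return f"b{lo}plus" if hi is None else f"b{lo}_{hi}"


@dataclass(frozen=True)
class ProximityConfig:
    """Radius, neighbor-count bins, and the cell classes entering the statistic."""

    radius: float = 30.0
    bins: tuple[tuple[int, int | None], ...] = DEFAULT_BINS
    reference_class: str = "TUMOR"
    neighbor_classes: tuple[str, ...] = IMMUNE_CLASSES

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not self.bins or self.bins[0][0] != 1:
            raise ValueError("bins must start at count 1")
        prev_hi = 0
        for lo, hi in self.bins:
            if lo != prev_hi + 1:
                raise ValueError("bins must be disjoint, ascending, and contiguous")
            if hi is not None and hi < lo:
                raise ValueError("bin upper edge below lower edge")
            prev_hi = np.inf if hi is None else hi
        if self.bins[-1][1] is not None:
            raise ValueError("last bin must be open-ended")

    @property
    def bin_labels(self) -> tuple[str, ...]:
        """All bin labels including the explicit zero-neighbor bin ``b0``."""
        return ("b0",) + tuple(_bin_label(lo, hi) for lo, hi in self.bins)


def _self_exclusion(counts, ref_ids, nbr_ids):
    if ref_ids is None or nbr_ids is None:
        return counts
    shared = np.isin(np.asarray(ref_ids), np.asarray(nbr_ids))
    return counts - shared.astype(counts.dtype)


def count_neighbors_within(
    reference_xy: np.ndarray,
    neighbor_xy: np.ndarray,
    radius: float,
    ref_ids=None,
    nbr_ids=None,
) -> np.ndarray:
    """Number of neighbor points within ``radius`` of each reference point.

    Euclidean center-to-center distance, inclusive boundary (d ≤ r).  When
    the two collections share members, pass ``ref_ids``/``nbr_ids`` so a
    point never counts itself.  Implemented with a k-d tree; the exhaustive
    :func:`brute_force_neighbor_counts` is the testing oracle.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    reference_xy = np.atleast_2d(np.asarray(reference_xy, dtype=float))
    neighbor_xy = np.atleast_2d(np.asarray(neighbor_xy, dtype=float))
    if len(reference_xy) == 0:
        return np.zeros(0, dtype=np.int64)
    if len(neighbor_xy) == 0:
        return np.zeros(len(reference_xy), dtype=np.int64)
    tree = cKDTree(neighbor_xy)
    counts = tree.query_ball_point(reference_xy, r=radius, return_length=True)
    counts = np.asarray(counts, dtype=np.int64)
    return _self_exclusion(counts, ref_ids, nbr_ids)


def brute_force_neighbor_counts(
    reference_xy: np.ndarray,
    neighbor_xy: np.ndarray,
    radius: float,
    ref_ids=None,
    nbr_ids=None,
) -> np.ndarray:
    """Exhaustive-pairwise oracle with the same contract as the k-d tree path."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    reference_xy = np.atleast_2d(np.asarray(reference_xy, dtype=float))
    neighbor_xy = np.atleast_2d(np.asarray(neighbor_xy, dtype=float))
    if len(reference_xy) == 0:
        return np.zeros(0, dtype=np.int64)
    if len(neighbor_xy) == 0:
        return np.zeros(len(reference_xy), dtype=np.int64)
    d = cdist(reference_xy, neighbor_xy)
    counts = (d <= radius).sum(axis=1).astype(np.int64)
    return _self_exclusion(counts, ref_ids, nbr_ids)


def bin_neighbor_counts(
    counts: np.ndarray, bins: tuple[tuple[int, int | None], ...] = DEFAULT_BINS
) -> np.ndarray:
    """Map integer neighbor counts to bin labels (0 → ``b0``)."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("neighbor counts must be nonnegative")
    labels = np.full(counts.shape, "b0", dtype=object)
    for lo, hi in bins:
        if hi is None:
            mask = counts >= lo
        else:
            mask = (counts >= lo) & (counts <= hi)
        labels[mask] = _bin_label(lo, hi)
    return labels


def build_proximity_table(
    labeled_cells: pd.DataFrame,
    region_set: RegionSet,
    config: ProximityConfig = ProximityConfig(),
) -> pd.DataFrame:
    """Per-region binned neighbor-count fractions and densities for one slide.

    Reference cells are attributed to their own region; the neighbor search
    runs over all non-excluded cells of the neighbor class anywhere on the
    slide.  Fractions are over the total reference cells of the region (NaN
    when a region has none, in which case densities are 0); densities use
    net region areas in mm².
    """
    cells = labeled_cells[labeled_cells["region"] != "EXCLUDED"]
    areas = region_set.areas()
    refs = cells[
        (cells["cell_class"] == config.reference_class)
        & cells["region"].isin(region_set.labels)
    ]
    ref_xy = refs[["x", "y"]].to_numpy(dtype=float)
    patient_id = labeled_cells["patient_id"].iloc[0]

    rows = []
    for neighbor_class in config.neighbor_classes:
        nbr = cells[cells["cell_class"] == neighbor_class]
        counts = count_neighbors_within(
            ref_xy,
            nbr[["x", "y"]].to_numpy(dtype=float),
            config.radius,
            ref_ids=refs["cell_id"].to_numpy() if neighbor_class == config.reference_class else None,
            nbr_ids=nbr["cell_id"].to_numpy() if neighbor_class == config.reference_class else None,
        )
        labels = bin_neighbor_counts(counts, config.bins)
        for region in region_set.labels:
            in_region = (refs["region"] == region).to_numpy()
            total = int(in_region.sum())
            for bin_label in config.bin_labels:
                n_in_bin = int((labels[in_region] == bin_label).sum())
                rows.append(
                    {
                        "patient_id": patient_id,
                        "region_label": region,
                        "neighbor_class": neighbor_class,
                        "bin_label": bin_label,
                        "n_reference_in_bin": n_in_bin,
                        "fraction": (n_in_bin / total) if total else np.nan,
                        "density": n_in_bin / areas[region],
                    }
                )
    return pd.DataFrame(rows, columns=PROXIMITY_COLUMNS)


def poisson_bin_probability(
    intensity: float, radius: float, bin: tuple[int, int | None]
) -> float:
    """Probability a neighbor-count bin is hit under the independence null.

    With neighbors a homogeneous Poisson process of ``intensity`` cells/mm²
    independent of the references, the count inside a disc of radius r μm is
    Poisson with mean μ = intensity·10⁻⁶·π·r², and the bin [lo, hi]
    probability is Σ_{k=lo..hi} e^{−μ} μᵏ / k!.
    """
    if intensity < 0:
        raise ValueError("intensity must be nonnegative")
    mu = intensity * 1e-6 * np.pi * radius**2
    lo, hi = bin
    if hi is None:
        return float(stats.poisson.sf(lo - 1, mu))
    return float(stats.poisson.cdf(hi, mu) - stats.poisson.cdf(lo - 1, mu))
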