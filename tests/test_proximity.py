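import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gliospatial.proximity import (
    ProximityConfig,
    bin_neighbor_counts,
    brute_force_neighbor_counts,
    build_proximity_table,
    count_neighbors_within,
    poisson_bin_probability,
)
from gliospatial.regions import Region, RegionSet, assign_cells_to_regions
from gliospatial.synthetic import ClusteringConfig, simulate_point_pattern
from gliospatial.io import SlideCellMap
from .conftest import cell_map_from, square


class TestNeighborCounts:
    def test_collinear_example(self):
        counts = count_neighbors_within(
            [[0, 0]], [[10, 0], [25, 0], [40, 0]], radius=30
        )
        assert counts.tolist() == [2]  # distances 10, 25 <= 30 < 40

    def test_boundary_distance_counted(self):
        assert count_neighbors_within([[0, 0]], [[30, 0]], 30).tolist() == [1]

    def test_empty_neighbor_set(self):
        assert count_neighbors_within([[0, 0], [5, 5]], np.zeros((0, 2)), 30).tolist() == [0, 0]

    def test_self_never_counted(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0]])
        ids = np.array(["a", "b"])
        counts = count_neighbors_within(xy, xy, 30, ref_ids=ids, nbr_ids=ids)
        assert counts.tolist() == [1, 1]

    def test_radius_larger_than_extent(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(0, 100, size=(20, 2))
        nbr = rng.uniform(0, 100, size=(35, 2))
        counts = count_neighbors_within(ref, nbr, radius=1e4)
        assert (counts == 35).all()

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_ref, n_nbr = rng.integers(1, 400, size=2)
        ref = rng.uniform(0, 1000, size=(n_ref, 2))
        nbr = rng.uniform(0, 1000, size=(n_nbr, 2))
        r = float(rng.uniform(5, 80))
        np.testing.assert_array_equal(
            count_neighbors_within(ref, nbr, r),
            brute_force_neighbor_counts(ref, nbr, r),
        )


class TestBins:
    def test_default_bin_edges(self):
        labels = bin_neighbor_counts([0, 1, 4, 5, 9, 10, 17])
        assert labels.tolist() == ["b0", "b1_4", "b1_4", "b5_9", "b5_9", "b10plus", "b10plus"]

    def test_config_validates_bins(self):
        with pytest.raises(ValueError):
            ProximityConfig(bins=((2, 4), (5, None)))  # must start at 1
        with pytest.raises(ValueError):
            ProximityConfig(bins=((1, 4), (6, None)))  # gap
        with pytest.raises(ValueError):
            ProximityConfig(radius=0)


class TestPoissonOracle:
    # frozen closed-form values at the core IBA1 intensity, r = 30 μm
    # (μ = 512e-6·π·900 ≈ 1.44765), cross-checked by Monte Carlo below
    FROZEN = {
        (0, 0): 0.23512314171730675,
        (1, 4): 0.7486586948871711,
        (5, 9): 0.016215152843657564,
        (10, None): 3.0105518646905693e-06,
    }

    @pytest.mark.parametrize("bin,expected", sorted(FROZEN.items(), key=str))
    def test_frozen_values(self, bin, expected):
        assert poisson_bin_probability(512.0, 30.0, bin) == pytest.approx(expected, rel=1e-9)

    def test_monte_carlo_cross_check(self):
        mu = 512e-6 * np.pi * 900
        draws = np.random.default_rng(0).poisson(mu, size=10**6)
        observed = ((draws >= 1) & (draws <= 4)).mean()
        assert observed == pytest.approx(self.FROZEN[(1, 4)], abs=3 * 5e-4)

    def test_zero_intensity(self):
        assert poisson_bin_probability(0.0, 30.0, (0, 0)) == 1.0
        assert poisson_bin_probability(0.0, 30.0, (1, 4)) == 0.0

    def test_open_bin_is_complement(self):
        mu_bins = [(0, 0), (1, 4), (5, 9)]
        closed = sum(poisson_bin_probability(512, 30, b) for b in mu_bins)
        assert poisson_bin_probability(512, 30, (10, None)) == pytest.approx(1 - closed)

    def test_monotone_in_intensity(self):
        probs = [1 - poisson_bin_probability(lam, 30, (0, 0)) for lam in (10, 100, 512, 2000)]
        assert probs == sorted(probs)


def _single_region_slide(cells_df, area_side=1000.0):
    cells_df = cells_df.copy()
    cells_df.insert(0, "cell_id", [f"c{i}" for i in range(len(cells_df))])
    cm = SlideCellMap("s", cells_df)
    rs = RegionSet("s", {"CORE": Region("CORE", square(0, 0, area_side))})
    return assign_cells_to_regions(cm, rs), rs


class TestProximityTable:
    def test_single_reference_with_three_neighbors(self):
        df = pd.DataFrame(
            {"x": [500, 505, 510, 495], "y": [500] * 4,
             "cell_class": ["TUMOR", "IBA1", "IBA1", "IBA1"]}
        )
        labeled, rs = _single_region_slide(df)
        pt = build_proximity_table(labeled, rs)
        row = pt.query("neighbor_class=='IBA1' and bin_label=='b1_4'")
        assert row["fraction"].iloc[0] == 1.0
        assert row["n_reference_in_bin"].iloc[0] == 1

    def test_cross_boundary_neighbor_counted(self, square_region_set):
        # tumor cell near the CORE/TRANSITION edge; its only IBA1 neighbor is
        # across the boundary: still counted, reference attributed to CORE
        cm = cell_map_from([(995, 500, "TUMOR"), (1005, 500, "IBA1")])
        labeled = assign_cells_to_regions(cm, square_region_set)
        pt = build_proximity_table(labeled, square_region_set)
        row = pt.query(
            "region_label=='CORE' and neighbor_class=='IBA1' and bin_label=='b1_4'"
        )
        assert row["fraction"].iloc[0] == 1.0

    def test_region_without_references_has_missing_fraction(self, square_region_set):
        cm = cell_map_from([(500, 500, "TUMOR"), (1500, 500, "IBA1")])
        labeled = assign_cells_to_regions(cm, square_region_set)
        pt = build_proximity_table(labeled, square_region_set)
        tz = pt.query("region_label=='TRANSITION' and neighbor_class=='IBA1'")
        assert tz["fraction"].isna().all()
        assert (tz["density"] == 0).all()

    def test_excluded_cells_dropped_both_sides(self):
        rs = RegionSet(
            "s",
            {"CORE": Region("CORE", square(0, 0, 1000), exclusions=(square(0, 0, 100),))},
        )
        cm = cell_map_from(
            [(50, 50, "TUMOR"), (500, 500, "TUMOR"), (520, 500, "IBA1"), (60, 60, "IBA1")]
        )
        labeled = assign_cells_to_regions(cm, rs)
        pt = build_proximity_table(labeled, rs)
        row = pt.query("neighbor_class=='IBA1'").set_index("bin_label")
        # one non-excluded reference with one non-excluded neighbor in range
        assert row.loc["b1_4", "n_reference_in_bin"] == 1
        assert row.loc["b1_4", "fraction"] == 1.0

    def test_fractions_sum_to_one(self, small_cohort):
        _, cohort = small_cohort
        pid = "P002"
        labeled = assign_cells_to_regions(cohort.cell_maps[pid], cohort.region_sets[pid])
        pt = build_proximity_table(labeled, cohort.region_sets[pid])
        sums = pt.groupby(["region_label", "neighbor_class"])["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0, rtol=1e-12)

    def test_positive_fraction_monotone_in_radius(self, small_cohort):
        _, cohort = small_cohort
        pid = "P003"
        labeled = assign_cells_to_regions(cohort.cell_maps[pid], cohort.region_sets[pid])
        prev = -1.0
        for r in (5.0, 15.0, 30.0, 60.0):
            pt = build_proximity_table(
                labeled, cohort.region_sets[pid], ProximityConfig(radius=r)
            )
            pos = pt.query("neighbor_class=='IBA1' and bin_label!='b0'")
            frac = pos.groupby("region_label")["fraction"].sum().mean()
            assert frac >= prev
            prev = frac


def test_thomas_clustering_exceeds_poisson_null():
    """With tumor-anchored immune recruitment ON, the fraction of tumor cells
    with any IBA1 neighbor within 30 μm exceeds the independence-null
    prediction (one-sided test over 20 seeds)."""
    region = Region("CORE", square(0, 0, 1000))
    rs = RegionSet("s", {"CORE": region})
    clustering = ClusteringConfig(enabled=True, classes=("IBA1",))
    lam = {"TUMOR": 2301.0, "IBA1": 512.0}
    null_positive = 1 - poisson_bin_probability(512.0, 30.0, (0, 0))
    excess = []
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        cells = simulate_point_pattern(region, lam, clustering, rng)
        cells.insert(0, "cell_id", [f"c{i}" for i in range(len(cells))])
        labeled = assign_cells_to_regions(SlideCellMap("s", cells), rs)
        pt = build_proximity_table(labeled, rs)
        pos = pt.query("neighbor_class=='IBA1' and bin_label!='b0'")["fraction"].sum()
        excess.append(pos - null_positive)
    t, p_two = stats.ttest_1samp(excess, 0.0)
    p_one = p_two / 2 if t > 0 else 1 - p_two / 2
    assert p_one < 0.01
    assert np.mean(excess) > 0
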