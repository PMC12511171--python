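import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gliospatial.inference import (
    compare_regions,
    km_estimate,
    median_split,
    run_survival_screen,
    univariate_cox,
    wilcoxon_signed_rank,
)
from gliospatial.synthetic import SurvivalModel, simulate_survival


def exact_signed_rank_p(diffs) -> float:
    """Independent oracle: two-sided exact p by enumeration of all 2ⁿ sign
    assignments of the observed |differences| (distinct, nonzero)."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    p_low = np.mean(ws <= w_obs)
    p_high = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_all_positive_n5(self):
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 1, 1, 1, 1])
        assert res.statistic == 15.0  # all five positive ranks
        assert res.p_value == pytest.approx(2 / 32)  # exact enumeration

    def test_identical_pairs_rejected(self):
        with pytest.raises(ValueError, match="no informative pairs"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=9), rng.normal(size=9)
        fwd, rev = wilcoxon_signed_rank(a, b), wilcoxon_signed_rank(b, a)
        assert fwd.p_value == pytest.approx(rev.p_value)
        n = fwd.n_used
        assert fwd.statistic + rev.statistic == n * (n + 1) / 2  # mirrored W

    @pytest.mark.parametrize("n", [3, 5, 8, 10])
    def test_exact_p_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            d = rng.normal(size=n)
            res = wilcoxon_signed_rank(d, np.zeros(n))
            assert res.method == "exact"
            assert res.p_value == pytest.approx(exact_signed_rank_p(d), abs=1e-12)

    def test_ties_fall_back_to_corrected_normal(self):
        a = np.array([3.0, 3.0, 3.0, 5.0, 5.0, 7.0, 2.0, 9.0])
        res = wilcoxon_signed_rank(a, np.zeros_like(a))
        assert res.method == "approx"
        assert 0 < res.p_value <= 1


def _paired_frame(values_by_patient):
    rows = []
    for pid, by_region in values_by_patient.items():
        for region, value in by_region.items():
            rows.append({"patient_id": pid, "region_label": region, "value": value})
    return pd.DataFrame(rows)


class TestCompareRegions:
    def test_missing_region_excluded_pairwise(self):
        data = {f"p{i}": {"CORE": 10 + i, "PERIPHERY": i} for i in range(6)}
        data["p9"] = {"CORE": 5.0}  # lacks periphery
        comp = compare_regions(_paired_frame(data), "tumor", ("CORE", "PERIPHERY"))
        assert comp.n_pairs == 6
        assert comp.p_value < 0.05
        assert comp.median_a > comp.median_b

    def test_too_few_pairs_is_error(self):
        data = {"p1": {"CORE": 1.0, "PERIPHERY": 2.0}, "p2": {"CORE": 3.0}}
        with pytest.raises(ValueError, match="informative pairs"):
            compare_regions(_paired_frame(data), "m", ("CORE", "PERIPHERY"))


class TestMedianSplit:
    def test_ties_go_low(self):
        labels, cutoff = median_split([1, 2, 3, 4, 5])
        assert cutoff == 3
        assert list(labels) == ["low", "low", "low", "high", "high"]

    def test_even_distinct_values_split_evenly(self):
        labels, _ = median_split([1.0, 2.0, 3.0, 4.0])
        assert (labels == "high").sum() == 2

    def test_degenerate_feature_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split([2.0, 2.0, 2.0])

    def test_missing_stays_missing(self):
        labels, _ = median_split([1.0, np.nan, 3.0, 4.0])
        assert labels[1] is None


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survival(self):
        times = np.array([2.0, 5.0, 7.0, 11.0, 13.0])
        curve = km_estimate(times, np.ones(5, dtype=bool))
        # product-limit with no censoring is the empirical survival function
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((times > t).mean())

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([3.0, 8.0], [False, False])
        assert (curve.survival == 1.0).all()
        assert curve.median is None

    def test_single_death(self):
        curve = km_estimate([14.0], [True])
        assert curve.survival[-1] == 0.0
        assert curve.median == 14.0


class TestUnivariateCox:
    def test_identical_groups_hr_one(self):
        times = np.tile([3.0, 6.0, 9.0, 12.0, 15.0, 18.0], 2)
        events = np.ones(12, dtype=bool)
        high = np.repeat([True, False], 6)
        res = univariate_cox(high, times, events)
        assert res.converged
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.ci95[0] <= res.hazard_ratio <= res.ci95[1]

    def test_relabel_inverts_hr(self):
        rng = np.random.default_rng(5)
        high = rng.uniform(size=40) < 0.5
        times = rng.exponential(10, size=40) * np.where(high, 2.0, 1.0)
        events = rng.uniform(size=40) < 0.8
        res = univariate_cox(high, times, events)
        inv = univariate_cox(~high, times, events)
        assert inv.hazard_ratio == pytest.approx(1 / res.hazard_ratio, rel=1e-6)
        assert inv.ci95 == pytest.approx((1 / res.ci95[1], 1 / res.ci95[0]), rel=1e-6)
        assert inv.p_value == pytest.approx(res.p_value, rel=1e-6)

    def test_strong_protective_effect_detected(self):
        rng = np.random.default_rng(8)
        high = np.arange(80) % 2 == 0
        model = SurvivalModel(log_hr=np.log(0.3), followup_months=(60.0, 60.0))
        surv = simulate_survival(high.astype(int), model, rng)
        res = univariate_cox(high, surv["os_months"], surv["os_event"])
        assert res.converged
        assert res.hazard_ratio < 1.0
        assert res.p_value < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            univariate_cox([True, True], [1.0, 2.0], [True, True])


class TestSurvivalScreen:
    def _clinical(self, n, rng):
        surv = simulate_survival(
            np.zeros(n, dtype=int), SurvivalModel(log_hr=0.0), rng
        )
        surv.insert(0, "patient_id", [f"p{i}" for i in range(n)])
        return surv

    def test_degenerate_feature_skipped_with_warning(self):
        rng = np.random.default_rng(0)
        clinical = self._clinical(20, rng)
        features = pd.DataFrame(
            {"flat": np.ones(20), "ok": rng.normal(size=20)},
            index=clinical["patient_id"],
        )
        with pytest.warns(UserWarning, match="flat"):
            screen = run_survival_screen(features, clinical)
        assert set(screen["feature"]) == {"ok"}
        assert set(screen["endpoint"]) == {"OS", "PFS"}

    def test_bh_adjustment_optional(self):
        rng = np.random.default_rng(1)
        clinical = self._clinical(30, rng)
        features = pd.DataFrame(
            rng.normal(size=(30, 4)),
            index=clinical["patient_id"],
            columns=[f"f{i}" for i in range(4)],
        )
        screen = run_survival_screen(features, clinical, adjust=True)
        assert "q_value" in screen.columns
        assert (screen["q_value"] >= screen["p_value"] - 1e-12).all()
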