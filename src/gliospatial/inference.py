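"""Cohort-level statistics.

Region contrasts use the paired two-sided Wilcoxon signed-rank test
(densities are heavily skewed across patients), with the classical
conventions: zero differences dropped, tied absolute differences given
average ranks, exact enumeration p for n ≤ 25 without ties and the
tie-corrected, continuity-corrected normal approximation otherwise.

The survival screen dichotomizes every per-patient feature at the cohort
median (pre-specified cutoff; "high" means strictly above the median) and
fits a univariate proportional-hazards model per feature and endpoint
(OS, PFS), with Efron handling of tied event times and Wald confidence
intervals.  P-values are reported raw — no multiplicity adjustment, though
Benjamini–Hochberg can be switched on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

__all__ = [
    "WilcoxonResult",
    "PairedComparison",
    "KMCurve",
    "SurvivalResult",
    "wilcoxon_signed_rank",
    "compare_regions",
    "median_split",
    "km_estimate",
    "univariate_cox",
    "run_survival_screen",
]


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W = sum of ranks of positive differences
    p_value: float
    n_used: int  # pairs remaining after zero-difference removal
    method: str  # "exact" or "approx"


def wilcoxon_signed_rank(a, b) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Returns W as the positive-rank sum.  Zero differences are dropped; with
    no informative (nonzero) pair the test is undefined and raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("no informative pairs: all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        correction=True,
        alternative="two-sided",
        method=method,
    )
    return WilcoxonResult(
        statistic=w_pos, p_value=float(res.pvalue), n_used=n, method=method
    )


@dataclass(frozen=True)
class PairedComparison:
    metric_name: str
    region_pair: tuple[str, str]
    n_pairs: int
    statistic: float
    p_value: float
    median_a: float
    median_b: float


def compare_regions(
    values: pd.DataFrame,
    metric_name: str,
    region_pair: tuple[str, str],
    value_col: str = "value",
) -> PairedComparison:
    """Paired region contrast of one per-patient metric.

    ``values`` is tidy with columns ``patient_id, region_label, <value_col>``
    already filtered to a single metric.  Pairs are assembled per patient;
    patients missing either region or either value are excluded pairwise.
    Region medians are reported over the included patients only.
    """
    region_a, region_b = region_pair
    wide = values.pivot_table(
        index="patient_id", columns="region_label", values=value_col, aggfunc="first"
    )
    for region in region_pair:
        if region not in wide.columns:
            wide[region] = np.nan
    paired = wide[[region_a, region_b]].dropna()
    if len(paired) < 2:
        raise ValueError(
            f"{metric_name} {region_a} vs {region_b}: fewer than 2 informative pairs"
        )
    res = wilcoxon_signed_rank(paired[region_a], paired[region_b])
    return PairedComparison(
        metric_name=metric_name,
        region_pair=region_pair,
        n_pairs=len(paired),
        statistic=res.statistic,
        p_value=res.p_value,
        median_a=float(paired[region_a].median()),
        median_b=float(paired[region_b].median()),
    )


def median_split(values) -> tuple[pd.Series, float]:
    """Dichotomize at the cohort median: high ⇔ value > median, ties to low.

    Missing values stay missing (excluded downstream).  Raises on an
    all-identical feature, which cannot be split.
    """
    values = pd.Series(values, dtype=float)
    non_missing = values.dropna()
    if len(non_missing) < 2:
        raise ValueError("median split needs at least 2 non-missing values")
    if non_missing.nunique() == 1:
        raise ValueError("degenerate split: all values identical")
    cutoff = float(non_missing.median())
    labels = pd.Series(
        np.where(values > cutoff, "high", "low"), index=values.index, dtype=object
    )
    labels[values.isna()] = None
    return labels, cutoff


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    median: float | None


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("km_estimate requires at least one observation")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    median = float(kmf.median_survival_time_)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).to_numpy(dtype=float)
    return KMCurve(
        times=surv.index.to_numpy(dtype=float),
        survival=surv.to_numpy(dtype=float),
        n_at_risk=at_risk,
        median=None if np.isinf(median) else median,
    )


@dataclass(frozen=True)
class SurvivalResult:
    feature_name: str
    endpoint: str  # "OS" or "PFS"
    cutoff: float
    n_high: int
    n_low: int
    hazard_ratio: float | None  # high vs low; None when the fit did not converge
    ci95: tuple[float, float] | None
    p_value: float | None
    log_hr: float | None
    se_log_hr: float | None
    converged: bool


def univariate_cox(
    high, times, events, feature_name: str = "feature", endpoint: str = "OS",
    cutoff: float = float("nan"),
) -> SurvivalResult:
    """Proportional-hazards fit of a single binary (high vs low) covariate.

    Efron handling of tied event times; HR = exp(coef); 95% CI from the
    Wald interval exp(coef ± 1.96·SE) with SE from the observed information;
    p from the Wald statistic.  Non-convergence (e.g. one group without
    events under complete separation) is reported explicitly through
    ``converged=False`` rather than as a number.
    """
    high = np.asarray(high)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n_high = int(high.sum())
    n_low = int(len(high) - n_high)
    if n_high == 0 or n_low == 0:
        raise ValueError("both high and low groups must be non-empty")
    if events.sum() == 0:
        raise ValueError("at least one event is required")
    df = pd.DataFrame(
        {"T": times, "E": events.astype(int), "high": high.astype(int)}
    )
    failed = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df, duration_col="T", event_col="E")
        coef = float(cph.params_["high"])
        se = float(cph.standard_errors_["high"])
        if not np.isfinite(coef) or not np.isfinite(se) or abs(coef) > 15:
            failed = "diverged"
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        failed = str(exc)
    if failed is not None:
        return SurvivalResult(
            feature_name=feature_name, endpoint=endpoint, cutoff=cutoff,
            n_high=n_high, n_low=n_low, hazard_ratio=None, ci95=None,
            p_value=None, log_hr=None, se_log_hr=None, converged=False,
        )
    z = coef / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SurvivalResult(
        feature_name=feature_name,
        endpoint=endpoint,
        cutoff=cutoff,
        n_high=n_high,
        n_low=n_low,
        hazard_ratio=float(np.exp(coef)),
        ci95=(float(np.exp(coef - 1.959963984540054 * se)),
              float(np.exp(coef + 1.959963984540054 * se))),
        p_value=p,
        log_hr=coef,
        se_log_hr=se,
        converged=True,
    )


def run_survival_screen(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    endpoints: tuple[str, ...] = ("OS", "PFS"),
    adjust: bool = False,
) -> pd.DataFrame:
    """Median-cutoff univariate survival screen over all features.

    ``features`` is wide, one row per patient (index or ``patient_id``
    column), one column per metric; ``clinical`` carries ``patient_id,
    os_months, os_event, pfs_months, pfs_event``.  Degenerate features are
    skipped with a warning, not a crash.  With ``adjust=True`` a
    Benjamini–Hochberg q-value column is added (off by default).
    """
    if "patient_id" in features.columns:
        features = features.set_index("patient_id")
    clinical = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    endpoint_cols = {"OS": ("os_months", "os_event"), "PFS": ("pfs_months", "pfs_event")}
    rows = []
    for feature_name in features.columns:
        values = features[feature_name]
        try:
            labels, cutoff = median_split(values)
        except ValueError as exc:
            warnings.warn(f"skipping feature {feature_name!r}: {exc}")
            continue
        keep = labels.notna() & labels.index.isin(clinical.index)
        for endpoint in endpoints:
            tcol, ecol = endpoint_cols[endpoint]
            aligned = clinical.loc[labels.index[keep]]
            result = univariate_cox(
                (labels[keep] == "high").to_numpy(),
                aligned[tcol].to_numpy(dtype=float),
                aligned[ecol].to_numpy(dtype=bool),
                feature_name=feature_name,
                endpoint=endpoint,
                cutoff=cutoff,
            )
            rows.append(
                {
                    "feature": result.feature_name,
                    "endpoint": result.endpoint,
                    "cutoff": result.cutoff,
                    "n_high": result.n_high,
                    "n_low": result.n_low,
                    "hazard_ratio": result.hazard_ratio,
                    "ci95_low": result.ci95[0] if result.ci95 else None,
                    "ci95_high": result.ci95[1] if result.ci95 else None,
                    "p_value": result.p_value,
                    "converged": result.converged,
                }
            )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        for endpoint in endpoints:
            mask = (out["endpoint"] == endpoint) & out["p_value"].notna()
            if mask.sum():
                out.loc[mask, "q_value"] = multipletests(
                    out.loc[mask, "p_value"], method="fdr_bh"
                )[1]
    return out
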