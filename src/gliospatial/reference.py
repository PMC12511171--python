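"""Published cohort characteristics of the underlying 54-patient study.

The study cohort of glioblastoma, IDH-wildtype patients is summarized here
by its published marginal counts and survival medians/ranges (patient-level
data are restricted).  :func:`published_cohort_records` reconstructs a
deterministic synthetic clinical table with exactly these marginals, so the
cohort-summary stage can be exercised against the printed characteristics:
52 dead / 2 alive, 30 patients under 65, 35 male / 19 female, 40 treated
with long-course radiotherapy + chemotherapy, median OS 14 months (range
1.7–192), median PFS 7.6 months (range 1.5–153).

Only the marginals are meaningful; the joint assignment of categories to
individual synthetic patients is an arbitrary deterministic interleaving.
"""

from __future__ import annotations

import numpy as np

from .io import ClinicalRecord

__all__ = ["PUBLISHED_COUNTS", "published_cohort_records"]

PUBLISHED_COUNTS: dict[str, dict[str, int]] = {
    "status": {"dead": 52, "alive": 2},
    "pfs_status": {"yes": 53, "no": 1},
    "age": {"under65": 30, "at_least65": 24},
    "sex": {"male": 35, "female": 19},
    "performance_status": {"ps0_2": 49, "gt2": 5},
    "midline": {"yes": 7, "none": 43, "missing": 4},
    "treatment": {"rt_chemo": 40, "palliative": 9, "none": 5},
    "mgmt": {"methylated": 32, "unmethylated": 19, "unknown": 3},
    "surgery": {"biopsy": 2, "partial": 30, "total": 22},
}
MEDIAN_OS, OS_RANGE = 14.0, (1.7, 192.0)
MEDIAN_PFS, PFS_RANGE = 7.6, (1.5, 153.0)


def _spread(n: int, lo: float, med: float, hi: float) -> np.ndarray:
    """n sorted values with the given min, max, and sample median (n even)."""
    half = n // 2
    lower = lo + (med - lo) * np.arange(half) / (half - 1)
    upper = med + (hi - med) * np.arange(half) / (half - 1)
    return np.concatenate([lower, upper])


def _interleave(levels: dict[str, int]) -> list[str]:
    """Deterministic assignment of categorical levels spread across the cohort."""
    out: list[str] = []
    for level, count in levels.items():
        out.extend([level] * count)
    # round-robin reshuffle so levels do not align across categoricals
    order = np.argsort(np.argsort([(i * 17) % len(out) for i in range(len(out))]))
    return [out[i] for i in order]


def published_cohort_records() -> list[ClinicalRecord]:
    """Deterministic 54-patient clinical table matching the published marginals."""
    n = 54
    os_months = _spread(n, *[OS_RANGE[0], MEDIAN_OS, OS_RANGE[1]])
    pfs_months = _spread(n, *[PFS_RANGE[0], MEDIAN_PFS, PFS_RANGE[1]])
    pfs_months = np.minimum(pfs_months, os_months)
    # the two alive patients are the longest-followed; the single patient
    # without progression-or-death is one of them
    os_event = np.ones(n, dtype=bool)
    os_event[-2:] = False
    pfs_event = np.ones(n, dtype=bool)
    pfs_event[-1] = False
    cats = {key: _interleave(levels) for key, levels in PUBLISHED_COUNTS.items()
            if key not in ("status", "pfs_status")}
    return [
        ClinicalRecord(
            patient_id=f"GBM{i + 1:02d}",
            os_months=float(os_months[i]),
            os_event=bool(os_event[i]),
            pfs_months=float(pfs_months[i]),
            pfs_event=bool(pfs_event[i]),
            age_group=cats["age"][i],
            sex=cats["sex"][i],
            performance_status=cats["performance_status"][i],
            treatment=cats["treatment"][i],
            mgmt=cats["mgmt"][i],
            surgery=cats["surgery"][i],
            midline=cats["midline"][i],
        )
        for i in range(n)
    ]
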