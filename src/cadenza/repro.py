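"""Visit-to-visit reproducibility statistics: ICC and within-subject CV.

The intraclass correlation coefficient follows the one-way random-effects
single-measure convention, ICC(1,1): with ``n`` subjects measured on
``k = 2`` visits,

    ICC = (BMS - WMS) / (BMS + (k - 1) WMS)

where BMS and WMS are the between- and within-subject mean squares of the
one-way ANOVA decomposition, with a p-value from F = BMS/WMS on
(n - 1, n(k - 1)) degrees of freedom.  A two-way mixed-effects variant,
ICC(3,1), is available behind a flag since the two conventions are often
conflated.  The within-subject coefficient of variation is the SD of a
subject's repeated measures divided by their mean, averaged over subjects.

Interpretation bands (Cicchetti for ICC): poor < 0.40 ≤ fair < 0.60 ≤
good < 0.75 ≤ excellent; CV: very good < 0.10 ≤ good < 0.20 ≤
acceptable < 0.30 ≤ not acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReproStats",
    "icc_1_1",
    "icc_3_1",
    "cv_within",
    "band",
    "icc_band",
    "cv_band",
    "repro_stats",
    "ICC_CUTS",
    "ICC_LABELS",
    "CV_CUTS",
    "CV_LABELS",
]

ICC_CUTS = (0.40, 0.60, 0.75)
ICC_LABELS = ("poor", "fair", "good", "excellent")
CV_CUTS = (0.10, 0.20, 0.30)
CV_LABELS = ("very good", "good", "acceptable", "not acceptable")


@dataclass(frozen=True)
class ReproStats:
    n_pairs: int
    icc: float
    icc_p: float
    icc_band: str
    cv_mean: float
    cv_band: str
    icc_variant: str = "ICC(1,1)"


def _paired(visit1: np.ndarray, visit2: np.ndarray) -> np.ndarray:
    v1 = np.asarray(visit1, dtype=float)
    v2 = np.asarray(visit2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("visits must have equal length")
    keep = np.isfinite(v1) & np.isfinite(v2)  # listwise deletion
    data = np.column_stack([v1[keep], v2[keep]])
    if len(data) < 3:
        raise ValueError("need at least 3 complete pairs")
    return data


def icc_1_1(visit1: np.ndarray, visit2: np.ndarray) -> tuple[float, float]:
    """One-way random-effects single-measure ICC with its F-test p-value."""
    data = _paired(visit1, visit2)
    n, k = data.shape
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance")
    subj_means = data.mean(axis=1)
    ss_between = k * np.sum((subj_means - grand) ** 2)
    ss_within = np.sum((data - subj_means[:, None]) ** 2)
    bms = ss_between / (n - 1)
    wms = ss_within / (n * (k - 1))
    if bms + (k - 1) * wms == 0:
        raise ValueError("degenerate variance decomposition")
    icc = (bms - wms) / (bms + (k - 1) * wms)
    if wms == 0:
        return float(icc), 0.0
    f = bms / wms
    p = float(stats.f.sf(f, n - 1, n * (k - 1)))
    return float(icc), p


def icc_3_1(visit1: np.ndarray, visit2: np.ndarray) -> tuple[float, float]:
    """Two-way mixed-effects single-measure consistency ICC, ICC(3,1)."""
    data = _paired(visit1, visit2)
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    visit_means = data.mean(axis=0)
    ss_between = k * np.sum((subj_means - grand) ** 2)
    ss_visits = n * np.sum((visit_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_between - ss_visits
    bms = ss_between / (n - 1)
    ems = ss_error / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems
    if denom == 0:
        raise ValueError("zero total variance")
    icc = (bms - ems) / denom
    if ems == 0:
        return float(icc), 0.0
    f = bms / ems
    p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


def cv_within(visit1: np.ndarray, visit2: np.ndarray) -> float:
    """Mean within-subject coefficient of variation over repeated measures."""
    data = _paired(visit1, visit2)
    means = data.mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("non-positive pair mean; CV undefined")
    sds = data.std(axis=1, ddof=1)
    return float(np.mean(sds / means))


def band(value: float, cuts: tuple[float, ...], labels: tuple[str, ...]) -> str:
    """Half-open interpretation binning: a cut value belongs to the upper band."""
    if list(cuts) != sorted(cuts):
        raise ValueError("cuts must be sorted")
    if len(labels) != len(cuts) + 1:
        raise ValueError("need one more label than cuts")
    return labels[int(np.searchsorted(cuts, value, side="right"))]


def icc_band(icc: float) -> str:
    return band(icc, ICC_CUTS, ICC_LABELS)


def cv_band(cv: float) -> str:
    return band(cv, CV_CUTS, CV_LABELS)


def repro_stats(
    visit1: np.ndarray, visit2: np.ndarray, icc_variant: str = "ICC(1,1)"
) -> ReproStats:
    """ICC + CV summary for one condition's paired visit measurements."""
    if icc_variant == "ICC(1,1)":
        icc, p = icc_1_1(visit1, visit2)
    elif icc_variant == "ICC(3,1)":
        icc, p = icc_3_1(visit1, visit2)
    else:
        raise ValueError("icc_variant must be 'ICC(1,1)' or 'ICC(3,1)'")
    cv = cv_within(visit1, visit2)
    n = int(np.sum(np.isfinite(np.asarray(visit1, float)) & np.isfinite(np.asarray(visit2, float))))
    return ReproStats(n, icc, p, icc_band(icc), cv, cv_band(cv), icc_variant)


def repro_table(
    df: pd.DataFrame,
    value: str = "ari",
    condition_cols: tuple[str, ...] = ("task_id", "hemisphere"),
    icc_variant: str = "ICC(1,1)",
) -> pd.DataFrame:
    """Per-condition reproducibility table from a long-format two-visit frame.

    ``df`` must have columns subject_id, visit (1/2), the condition
    columns and the value column.
    """
    rows = []
    for keys, g in df.groupby(list(condition_cols)):
        wide = g.pivot_table(index="subject_id", columns="visit", values=value)
        if not {1, 2}.issubset(wide.columns):
            continue
        try:
            st = repro_stats(wide[1].to_numpy(), wide[2].to_numpy(), icc_variant)
        except ValueError:
            continue
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append(
            dict(zip(condition_cols, keys))
            | {
                "n_pairs": st.n_pairs,
                "icc": st.icc,
                "icc_p": st.icc_p,
                "icc_band": st.icc_band,
                "cv_mean": st.cv_mean,
                "cv_band": st.cv_band,
                "icc_variant": st.icc_variant,
            }
        )
    return pd.DataFrame(rows)
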