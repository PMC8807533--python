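"""Group statistics over per-cell measurements.

Mirrors the study's statistical treatment: per-condition violin-style
summaries with per-field medians, two-sided Mann-Whitney U comparisons
between conditions (exact by enumeration for small samples, tie-corrected
normal approximation with continuity correction otherwise), and the
per-cell joint activity-by-length table with per-condition Spearman rank
correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "TreatmentSummary",
    "ComparisonResult",
    "summarize",
    "mann_whitney_u",
    "compare_conditions",
    "activity_length_table",
    "significance_stars",
    "EXACT_PRODUCT_THRESHOLD",
]

# exact enumeration when n_a * n_b <= this; normal approximation above
EXACT_PRODUCT_THRESHOLD = 100

MEASUREMENTS = ["erk_activity", "process_length_px"]


@dataclass
class TreatmentSummary:
    condition: str
    n_cells: int
    n_fields: int
    median_activity: float
    sd_activity: float
    median_length_px: float
    sd_length_px: float
    field_medians_activity: list[float]
    field_medians_length: list[float]


@dataclass
class ComparisonResult:
    condition_a: str
    condition_b: str
    measurement: str
    U_statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str
    stars: str


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize(records: pd.DataFrame) -> list[TreatmentSummary]:
    """Per-condition pooled medians/SDs plus per-field median vectors.

    Expects QC-passing records only (callers filter on ``qc_pass``).
    Conditions with zero cells yield a row with null statistics.
    Deterministic: conditions sorted, field medians ordered by field_id.
    """
    out: list[TreatmentSummary] = []
    if records.empty:
        return out
    for condition, grp in records.groupby("condition", sort=True):
        act = grp["erk_activity"].astype(float).dropna()
        ln = grp["process_length_px"].astype(float).dropna()
        fm_act, fm_len = [], []
        for _, fgrp in grp.groupby("field_id", sort=True):
            fm_act.append(float(fgrp["erk_activity"].median()))
            fm_len.append(float(fgrp["process_length_px"].median()))
        n = len(grp)
        out.append(TreatmentSummary(
            condition=condition,
            n_cells=n,
            n_fields=grp["field_id"].nunique(),
            median_activity=float(act.median()) if n else np.nan,
            sd_activity=float(act.std(ddof=1)) if len(act) > 1 else np.nan,
            median_length_px=float(ln.median()) if n else np.nan,
            sd_length_px=float(ln.std(ddof=1)) if len(ln) > 1 else np.nan,
            field_medians_activity=fm_act,
            field_medians_length=fm_len,
        ))
    return out


def summaries_to_frame(summaries: list[TreatmentSummary]) -> pd.DataFrame:
    cols = list(TreatmentSummary.__dataclass_fields__)
    return pd.DataFrame([s.__dict__ for s in summaries], columns=cols)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a from midrank sums: R_a - n_a (n_a + 1) / 2."""
    n_a = len(a)
    ranks = sps.rankdata(np.concatenate([a, b]))
    return float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all group assignments.

    Conditions on the observed pooled values (so ties are handled
    exactly): every C(n, n_a) choice of which pooled ranks form group a is
    equally likely under the null. p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n, n_a = len(pooled), len(a)
    offset = n_a * (n_a + 1) / 2.0
    n_le = 0
    n_ge = 0
    eps = 1e-9
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - offset
        if u <= u_obs + eps:
            n_le += 1
        if u >= u_obs - eps:
            n_ge += 1
    total = comb(n, n_a)
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def mann_whitney_u(values_a, values_b) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U_a, p, method)`` with U computed from midrank sums for
    group a (so swapping groups maps U to n_a*n_b - U with the same p).
    Exact enumeration over all group assignments when
    ``n_a * n_b <= EXACT_PRODUCT_THRESHOLD``; otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    Two groups with all values identical give p = 1 (logged).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.info("all values identical across both groups: p = 1")
        return u, 1.0, "degenerate"
    if a.size * b.size <= EXACT_PRODUCT_THRESHOLD:
        return u, _exact_p(a, b, u), "exact"
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return u, float(res.pvalue), "asymptotic"


def compare_conditions(
    records: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    measurement: str,
) -> ComparisonResult:
    """Mann-Whitney comparison of one measurement between two conditions."""
    va = records.loc[records["condition"] == condition_a, measurement] \
        .astype(float).dropna().to_numpy()
    vb = records.loc[records["condition"] == condition_b, measurement] \
        .astype(float).dropna().to_numpy()
    u, p, method = mann_whitney_u(va, vb)
    return ComparisonResult(
        condition_a=condition_a, condition_b=condition_b,
        measurement=measurement, U_statistic=u, p_value=p,
        n_a=len(va), n_b=len(vb), method=method,
        stars=significance_stars(p),
    )


def comparisons_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    cols = list(ComparisonResult.__dataclass_fields__)
    return pd.DataFrame([r.__dict__ for r in results], columns=cols)


def activity_length_table(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell joint (activity, length) table plus per-condition Spearman.

    Returns ``(table, correlations)``. The table has one row per cell
    (field_id, cell_id, condition, erk_activity, process_length_px). The
    correlation frame has per condition the Spearman rho and p between
    activity and length; a condition where either variable is constant
    yields null values with a reason.
    """
    cols = ["field_id", "cell_id", "condition", "erk_activity",
            "process_length_px"]
    table = records[cols].reset_index(drop=True)
    rows = []
    for condition, grp in table.groupby("condition", sort=True):
        act = grp["erk_activity"].astype(float).to_numpy()
        ln = grp["process_length_px"].astype(float).to_numpy()
        row = {"condition": condition, "n_cells": len(grp),
               "spearman_rho": np.nan, "spearman_p": np.nan, "reason": ""}
        if len(grp) < 3:
            row["reason"] = "too_few_cells"
        elif np.all(act == act[0]) or np.all(ln == ln[0]):
            row["reason"] = "constant_input"
        else:
            rho, p = sps.spearmanr(act, ln)
            row["spearman_rho"] = float(rho)
            row["spearman_p"] = float(p)
        rows.append(row)
    return table, pd.DataFrame(rows)
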