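"""Quality control of per-cell measurements.

Filtering is flag-based and reversible: QC never deletes rows or mutates
measurement values, it only updates ``qc_pass``/``qc_reason``. Geometry
gates catch incorrectly recognized cells (border-clipped cells, implausible
areas or nucleus fractions); an outlier rule (Tukey IQR by default) is then
applied per condition to chosen measurement columns.

Quartiles use linear interpolation (numpy default, type 7); the flag
boundary depends on this convention, so it is pinned here and in tests.
Values exactly on an IQR fence pass (strict inequality flags).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["QcParams", "flag_geometry", "flag_outliers", "qc_report"]


@dataclass
class QcParams:
    remove_border_cells: bool = True
    area_gate: tuple[float, float] = (100.0, 20000.0)
    nucleus_fraction_gate: tuple[float, float] = (0.02, 0.9)
    outlier_rule: str = "iqr"  # "iqr" | "percentile"
    iqr_multiplier: float = 1.5
    percentile_bounds: tuple[float, float] = (1.0, 99.0)
    apply_outlier_to: list[str] = field(
        default_factory=lambda: ["erk_activity", "process_length_px"])

    def __post_init__(self) -> None:
        for name in ("area_gate", "nucleus_fraction_gate", "percentile_bounds"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be an ordered pair")
        if self.iqr_multiplier <= 0:
            raise ValueError("iqr_multiplier must be > 0")
        if self.outlier_rule not in ("iqr", "percentile"):
            raise ValueError("outlier_rule must be 'iqr' or 'percentile'")


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    # CSV round trips turn empty reason strings into NaN
    df["qc_reason"] = df["qc_reason"].fillna("").astype(str)
    df["qc_pass"] = df["qc_pass"].astype(bool)
    return df


def _add_flag(df: pd.DataFrame, rows: pd.Series, reason: str) -> None:
    df.loc[rows, "qc_pass"] = False
    existing = df.loc[rows, "qc_reason"]
    df.loc[rows, "qc_reason"] = np.where(
        existing.astype(str).str.len() > 0, existing + ";" + reason, reason)


def flag_geometry(records: pd.DataFrame, params: QcParams) -> pd.DataFrame:
    """Flag border-clipped cells and cells outside geometry gates.

    Returns a copy with updated ``qc_pass``/``qc_reason``; reason codes are
    ``border``, ``area_gate`` and ``nucleus_fraction``, semicolon-joined
    when several apply.
    """
    df = records.copy()
    if df.empty:
        return df
    _normalize(df)
    if params.remove_border_cells:
        _add_flag(df, df["touches_border"].astype(bool), "border")
    lo, hi = params.area_gate
    area = df["cell_area_px2"].astype(float)
    _add_flag(df, (area < lo) | (area > hi), "area_gate")
    lo, hi = params.nucleus_fraction_gate
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = df["nucleus_area_px2"].astype(float) / area
    _add_flag(df, (frac < lo) | (frac > hi) | ~np.isfinite(frac),
              "nucleus_fraction")
    return df


def flag_outliers(records: pd.DataFrame, params: QcParams) -> pd.DataFrame:
    """Flag per-condition outliers in the listed measurement columns.

    IQR rule: values outside ``[Q1 - m*IQR, Q3 + m*IQR]`` within a
    (condition, column) group are flagged (fences computed from rows that
    currently pass QC; identical values collapse the fences onto the value
    itself and equality passes). Percentile rule: outside the stated
    percentile bounds. Groups with fewer than 4 passing records skip the
    rule with a logged warning. Flags are OR-combined with existing flags
    and are invariant to row order.
    """
    df = records.copy()
    if df.empty:
        return df
    _normalize(df)
    for condition, grp in df.groupby("condition", sort=True):
        passing = grp[grp["qc_pass"]]
        for col in params.apply_outlier_to:
            vals = passing[col].astype(float).dropna()
            if len(vals) < 4:
                logger.warning(
                    "outlier rule skipped for condition %r column %r: "
                    "only %d passing records", condition, col, len(vals))
                continue
            if params.outlier_rule == "iqr":
                q1, q3 = np.quantile(vals, [0.25, 0.75])  # linear, type 7
                iqr = q3 - q1
                lo = q1 - params.iqr_multiplier * iqr
                hi = q3 + params.iqr_multiplier * iqr
            else:
                lo, hi = np.percentile(vals, params.percentile_bounds)
            col_vals = df.loc[grp.index, col].astype(float)
            bad = grp.index[(col_vals < lo) | (col_vals > hi)]
            _add_flag(df, df.index.isin(bad), f"outlier_{col}")
    return df


def qc_report(records: pd.DataFrame) -> pd.DataFrame:
    """Per-condition pass/fail counts broken down by reason code."""
    rows = []
    for condition, grp in records.groupby("condition", sort=True):
        reasons: dict[str, int] = {}
        for joined in grp.loc[~grp["qc_pass"], "qc_reason"]:
            for reason in str(joined).split(";"):
                if reason:
                    reasons[reason] = reasons.get(reason, 0) + 1
        row = {"condition": condition, "n_cells": len(grp),
               "n_pass": int(grp["qc_pass"].sum()),
               "n_fail": int((~grp["qc_pass"]).sum())}
        row.update({f"fail_{k}": v for k, v in sorted(reasons.items())})
        rows.append(row)
    report = pd.DataFrame(rows).fillna(0)
    for col in report.columns:
        if col.startswith(("fail_", "n_")):
            report[col] = report[col].astype(int)
    return report
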