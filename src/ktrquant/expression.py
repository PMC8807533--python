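"""Relative qPCR expression via the comparative Ct (ddCt) method.

Per replicate, the target gene's Ct is normalized against a reference gene
measured in the same sample (dCt = Ct_target - Ct_reference). The
treated-vs-control difference of mean dCt is ddCt, and the fold change is
2**(-ddCt); results are reported as log2 fold change with a t-based 95%
confidence interval on the two-sample dCt difference, and a two-sample
t-test p-value (Welch by default, pooled-variance Student available).

Plate-shift invariance holds by construction: adding a constant to every
Ct of one replicate cancels in dCt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ExpressionResult", "PairingError", "delta_delta_ct",
           "results_to_frame"]

QPCR_COLUMNS = ["gene", "condition", "replicate", "ct"]


class PairingError(ValueError):
    """A (condition, replicate) lacks its reference-gene measurement."""


@dataclass
class ExpressionResult:
    gene: str
    condition: str
    log_fold_change: float
    fold_change: float
    ci95_low: float
    ci95_high: float
    p_value: float
    n_replicates: int
    log_base: int


def _welch_df(s1: float, n1: int, s2: float, n2: int) -> float:
    v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
    if v1 + v2 == 0:
        return n1 + n2 - 2
    return (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))


def delta_delta_ct(
    records: pd.DataFrame,
    reference_gene: str = "GAPDH",
    control_condition: str = "DMSO",
    equal_var: bool = False,
    log_base: int = 2,
) -> list[ExpressionResult]:
    """ddCt analysis of a long-format Ct table.

    ``records`` needs columns ``gene, condition, replicate, ct``. Every
    (condition, replicate) must include the reference gene, else
    :class:`PairingError` names the gap. For each target gene and each
    non-control condition: ddCt = mean dCt(treated) - mean dCt(control),
    log2 fold change = -ddCt, with a 95% CI from the t distribution on the
    two-sample dCt difference (Welch-Satterthwaite df unless
    ``equal_var``) and a two-sample t-test p-value on the dCt values.
    ``log_base=10`` rescales the reported log fold change and CI.
    """
    df = records.copy()
    missing_cols = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    if log_base not in (2, 10):
        raise ValueError("log_base must be 2 or 10")
    if control_condition not in set(df["condition"]):
        raise ValueError(f"control condition {control_condition!r} absent")

    ref = df[df["gene"] == reference_gene].set_index(["condition", "replicate"])
    targets = df[df["gene"] != reference_gene]
    gaps = [key for key in
            targets.set_index(["condition", "replicate"]).index.unique()
            if key not in ref.index]
    if gaps:
        raise PairingError(
            f"reference gene {reference_gene!r} missing for "
            f"(condition, replicate) pairs: {sorted(gaps)}")

    dct = targets.copy()
    dct["dct"] = dct["ct"].to_numpy() - ref.loc[
        list(zip(dct["condition"], dct["replicate"])), "ct"].to_numpy()

    scale = 1.0 if log_base == 2 else np.log10(2.0)
    results: list[ExpressionResult] = []
    for gene, ggrp in dct.groupby("gene", sort=True):
        ctrl = ggrp.loc[ggrp["condition"] == control_condition, "dct"] \
            .astype(float).to_numpy()
        if ctrl.size == 0:
            raise PairingError(f"no control-condition replicates for {gene!r}")
        for condition, cgrp in ggrp.groupby("condition", sort=True):
            if condition == control_condition:
                continue
            treated = cgrp["dct"].astype(float).to_numpy()
            n_t, n_c = treated.size, ctrl.size
            ddct = treated.mean() - ctrl.mean()
            log2fc = -ddct
            s_t = treated.std(ddof=1) if n_t > 1 else 0.0
            s_c = ctrl.std(ddof=1) if n_c > 1 else 0.0
            se = np.sqrt(s_t ** 2 / n_t + s_c ** 2 / n_c)
            if equal_var:
                dof = n_t + n_c - 2
                sp2 = (((n_t - 1) * s_t ** 2 + (n_c - 1) * s_c ** 2) / dof
                       if dof > 0 else 0.0)
                se = np.sqrt(sp2 * (1 / n_t + 1 / n_c))
            else:
                dof = _welch_df(s_t, n_t, s_c, n_c)
            if se > 0 and dof > 0:
                half = sps.t.ppf(0.975, dof) * se
                tres = sps.ttest_ind(treated, ctrl, equal_var=equal_var)
                p = float(tres.pvalue)
            else:
                half = 0.0
                p = 1.0 if ddct == 0 else 0.0
            results.append(ExpressionResult(
                gene=gene, condition=condition,
                log_fold_change=log2fc * scale,
                fold_change=float(2.0 ** (-ddct)),
                ci95_low=(log2fc - half) * scale,
                ci95_high=(log2fc + half) * scale,
                p_value=p,
                n_replicates=min(n_t, n_c),
                log_base=log_base,
            ))
    return results


def results_to_frame(results: list[ExpressionResult]) -> pd.DataFrame:
    cols = list(ExpressionResult.__dataclass_fields__)
    return pd.DataFrame([r.__dict__ for r in results], columns=cols)
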