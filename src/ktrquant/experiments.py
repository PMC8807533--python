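"""Canned recovery and discrimination experiments on synthetic fields.

Each function simulates fields with known ground truth, runs the full
measurement pipeline on them, and scores recovery. They are the package's
self-validation experiments: segmentation fidelity, activity-ratio and
process-length parameter recovery, the two-arm discrimination design
(6 fields and >= 300 cells per arm, mirroring the study layout), and a
qPCR simulation with a planted induction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .benchmark import paired_measurements, segmentation_scores
from .pipeline import field_seed
from .qc import QcParams, flag_geometry, flag_outliers
from .quantify import MorphologyParams, measure_field, records_to_frame
from .segmentation import SegmentationParams, segment_cells, segment_nuclei
from .stats import mann_whitney_u
from .synthetic import SceneSpec, generate_field, scene_for_condition

__all__ = [
    "run_field", "segmentation_benchmark", "activity_recovery_experiment",
    "length_recovery_experiment", "discrimination_run", "simulate_qpcr_table",
]


def run_field(spec: SceneSpec, field_id="f0", condition="",
              seg_params: SegmentationParams | None = None,
              morph_params: MorphologyParams | None = None):
    """Generate one field and run segmentation + measurement on it."""
    seg_params = seg_params or SegmentationParams()
    morph_params = morph_params or MorphologyParams()
    field, gt, true_nuc, true_cell = generate_field(spec, field_id, condition)
    nuclei = segment_nuclei(field.dna, seg_params)
    cells = segment_cells(field.reporter, nuclei, seg_params)
    records = records_to_frame(
        measure_field(field, nuclei, cells, seg_params, morph_params))
    records["field_id"] = field_id
    records["condition"] = condition
    return {
        "field": field, "gt": gt, "true_nuc": true_nuc,
        "true_cell": true_cell, "nuclei": nuclei, "cells": cells,
        "records": records,
    }


def segmentation_benchmark(seed: int, n_fields: int = 2) -> dict:
    """Nucleus detection recall/precision and cell-mask Jaccard at defaults."""
    recalls, precisions, jaccards = [], [], []
    n_cells = 0
    for i in range(n_fields):
        r = run_field(SceneSpec(rng_seed=field_seed(seed, i)), f"f{i}")
        s = segmentation_scores(r["true_nuc"], r["nuclei"],
                                r["true_cell"], r["cells"])
        recalls.append(s["recall"])
        precisions.append(s["precision"])
        jaccards.extend(s["cell_jaccards"])
        n_cells += s["n_true"]
    return {
        "recall": float(np.mean(recalls)),
        "precision": float(np.mean(precisions)),
        "cell_jaccard_median": float(np.median(jaccards)),
        "n_cells": n_cells,
    }


def activity_recovery_experiment(seed: int, n_fields: int = 2) -> dict:
    """Recover per-cell C/N ratios drawn uniformly from [0.5, 3].

    Default noise; >= 100 cells across fields. Reports the median absolute
    relative error and the Spearman correlation of true vs measured ratio.
    """
    frames = []
    for i in range(n_fields):
        spec = SceneSpec(rng_seed=field_seed(seed, 100 + i),
                         activity_ratio=(0.5, 3.0),
                         activity_ratio_dist="uniform")
        r = run_field(spec, f"act{i}")
        frames.append(paired_measurements(r["gt"], r["true_nuc"],
                                          r["nuclei"], r["records"]))
    paired = pd.concat(frames, ignore_index=True)
    rel_err = ((paired["erk_activity"] - paired["true_activity_ratio"]).abs()
               / paired["true_activity_ratio"])
    rho = spearmanr(paired["true_activity_ratio"],
                    paired["erk_activity"]).statistic
    return {
        "median_abs_rel_error": float(rel_err.median()),
        "spearman_rho": float(rho),
        "n_cells": int(len(paired)),
    }


def length_recovery_experiment(seed: int, n_fields: int = 2) -> dict:
    """Recover single-process lengths drawn uniformly from [0, 120] px.

    Cells are compact (cytoplasm inside the body disc) so the skeleton
    isolates the process contribution; default noise. Reports the Pearson
    correlation of true vs measured length.
    """
    frames = []
    for i in range(n_fields):
        spec = SceneSpec(rng_seed=field_seed(seed, 200 + i),
                         image_height_px=1024, image_width_px=1024,
                         n_cells=40, cytoplasm_radius_px=(7.0, 9.0),
                         n_processes_per_cell=(1, 1),
                         process_length_px=(0.0, 120.0),
                         process_length_dist="uniform")
        r = run_field(spec, f"len{i}")
        frames.append(paired_measurements(r["gt"], r["true_nuc"],
                                          r["nuclei"], r["records"]))
    paired = pd.concat(frames, ignore_index=True)
    rr = pearsonr(paired["true_process_length_px"],
                  paired["process_length_px"]).statistic
    return {"pearson_r": float(rr), "n_cells": int(len(paired))}


def discrimination_run(seed: int, n_fields_per_arm: int = 6,
                       qc_params: QcParams | None = None) -> dict:
    """One control-vs-inhibitor experiment mirroring the study design.

    Each arm has ``n_fields_per_arm`` fields of the default 55-cell scene
    (>= 300 cells per arm). Records pass geometry + outlier QC, then both
    measurements are compared between arms with the Mann-Whitney U test.
    """
    qc_params = qc_params or QcParams()
    base = SceneSpec()
    frames = []
    idx = 0
    for arm, preset in (("control", "control"), ("inhibitor", "inhibitor")):
        for j in range(n_fields_per_arm):
            spec = scene_for_condition(base, preset,
                                       rng_seed=field_seed(seed, 300 + idx))
            r = run_field(spec, f"{arm}_f{j}", condition=arm)
            frames.append(r["records"])
            idx += 1
    records = pd.concat(frames, ignore_index=True)
    qced = flag_outliers(flag_geometry(records, qc_params), qc_params)
    passing = qced[qced["qc_pass"]]
    out = {"n_control": int((passing["condition"] == "control").sum()),
           "n_inhibitor": int((passing["condition"] == "inhibitor").sum()),
           "records": passing}
    for meas in ("erk_activity", "process_length_px"):
        a = passing.loc[passing["condition"] == "control", meas].dropna()
        b = passing.loc[passing["condition"] == "inhibitor", meas].dropna()
        u, p, _ = mann_whitney_u(a.to_numpy(), b.to_numpy())
        out[f"p_{meas}"] = p
        out[f"U_{meas}"] = u
    return out


def simulate_qpcr_table(seed: int, fold: float = 4.0, sd: float = 0.2,
                        gene: str = "MYOG", n_replicates: int = 3
                        ) -> pd.DataFrame:
    """Triplicate Ct table with a planted induction of ``fold`` in SCH."""
    rng = np.random.default_rng(seed)
    rows = []
    for cond in ("DMSO", "SCH"):
        for rep in range(n_replicates):
            rows.append({"gene": "GAPDH", "condition": cond, "replicate": rep,
                         "ct": 15.0 + rng.normal(0, sd)})
            bump = -np.log2(fold) if cond == "SCH" else 0.0
            rows.append({"gene": gene, "condition": cond, "replicate": rep,
                         "ct": 20.0 + bump + rng.normal(0, sd)})
    return pd.DataFrame(rows)
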