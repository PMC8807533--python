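"""Ground-truth matching and recovery scoring for synthetic fields.

Measured label maps are raster-ordered and do not share ids with the
generator's ground truth, so recovery experiments first establish a
one-to-one correspondence between true and estimated objects by
intersection-over-union, then pair measurements cell by cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix

from .containers import LabelMap

__all__ = ["match_labels", "mask_iou", "segmentation_scores",
           "paired_measurements"]


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 0.0


def match_labels(
    true_labels: np.ndarray,
    est_labels: np.ndarray,
    iou_threshold: float = 0.5,
) -> dict[int, tuple[int, float]]:
    """One-to-one greedy IoU matching of true to estimated labels.

    Overlapping (true, est) pairs are ranked by IoU; pairs are accepted
    greedily while both labels are unused and IoU exceeds the threshold.
    Returns ``{true_id: (est_id, iou)}``.
    """
    t = np.asarray(true_labels).ravel()
    e = np.asarray(est_labels).ravel()
    both = (t > 0) & (e > 0)
    if not both.any():
        return {}
    nt = int(t.max()) + 1
    ne = int(e.max()) + 1
    inter = coo_matrix((np.ones(both.sum()), (t[both], e[both])),
                       shape=(nt, ne)).tocsr()
    area_t = np.bincount(t[t > 0], minlength=nt)
    area_e = np.bincount(e[e > 0], minlength=ne)
    ti, ei = inter.nonzero()
    ov = np.asarray(inter[ti, ei]).ravel()
    iou = ov / (area_t[ti] + area_e[ei] - ov)
    order = np.argsort(-iou)
    used_t: set[int] = set()
    used_e: set[int] = set()
    out: dict[int, tuple[int, float]] = {}
    for idx in order:
        if iou[idx] <= iou_threshold:
            break
        a, b = int(ti[idx]), int(ei[idx])
        if a in used_t or b in used_e:
            continue
        used_t.add(a)
        used_e.add(b)
        out[a] = (b, float(iou[idx]))
    return out


def segmentation_scores(
    true_nuclei: LabelMap,
    est_nuclei: LabelMap,
    true_cells: LabelMap,
    est_cells: LabelMap,
    iou_threshold: float = 0.5,
) -> dict:
    """Nucleus detection recall/precision and matched-cell Jaccard values."""
    nuc_match = match_labels(true_nuclei.labels, est_nuclei.labels,
                             iou_threshold)
    n_true = true_nuclei.ids.size
    n_est = est_nuclei.ids.size
    jaccards = []
    for true_id, (est_id, _) in nuc_match.items():
        jaccards.append(mask_iou(true_cells.labels == true_id,
                                 est_cells.labels == est_id))
    return {
        "n_true": int(n_true),
        "n_est": int(n_est),
        "n_matched": len(nuc_match),
        "recall": len(nuc_match) / n_true if n_true else np.nan,
        "precision": len(nuc_match) / n_est if n_est else np.nan,
        "cell_jaccards": np.asarray(jaccards),
        "nucleus_match": nuc_match,
    }


def paired_measurements(
    ground_truth: pd.DataFrame,
    true_nuclei: LabelMap,
    est_nuclei: LabelMap,
    records: pd.DataFrame,
) -> pd.DataFrame:
    """Join ground truth with measurements for IoU-matched cells.

    Returns one row per matched cell with ``true_activity_ratio``,
    ``true_process_length_px`` and the measured columns.
    """
    match = match_labels(true_nuclei.labels, est_nuclei.labels)
    meas = records.set_index("cell_id")
    rows = []
    for _, gt_row in ground_truth.iterrows():
        got = match.get(int(gt_row["cell_id"]))
        if got is None or got[0] not in meas.index:
            continue
        m = meas.loc[got[0]]
        rows.append({
            "true_cell_id": int(gt_row["cell_id"]),
            "est_cell_id": got[0],
            "iou": got[1],
            "true_activity_ratio": gt_row["true_activity_ratio"],
            "true_process_length_px": gt_row["true_process_length_px"],
            "erk_activity": m["erk_activity"],
            "process_length_px": m["process_length_px"],
            "qc_pass": m["qc_pass"],
        })
    return pd.DataFrame(rows)
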