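"""Per-cell activity-ratio and process-length measurements."""

import numpy as np
import pytest
from skimage.morphology import disk

from ktrquant import (LabelMap, MorphologyParams, SceneSpec, cell_body_mask,
                      erk_activity, generate_field, process_length,
                      segment_cells, segment_nuclei)
from ktrquant.benchmark import paired_measurements
from ktrquant.quantify import IntegrityError, measure_field, records_to_frame

from conftest import noiseless


def circle_mask(shape, center, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def test_uniform_reporter_gives_ratio_one():
    shape = (64, 64)
    nuc = circle_mask(shape, (32, 32), 6)
    cell = circle_mask(shape, (32, 32), 12)
    reporter = np.full(shape, 123.0)
    ratio, mn, mc, reason = erk_activity(reporter, nuc, cell)
    assert ratio == 1.0 and reason is None and mn == mc == 123.0


def test_ratio_scale_invariance(rng):
    shape = (64, 64)
    nuc = circle_mask(shape, (32, 32), 6)
    cell = circle_mask(shape, (32, 32), 12)
    reporter = rng.uniform(1, 200, shape)
    r1, *_ = erk_activity(reporter, nuc, cell)
    r2, *_ = erk_activity(reporter * 7.3, nuc, cell)
    assert r2 == pytest.approx(r1, rel=1e-12)


def test_empty_cytoplasm_flagged_not_crashed():
    shape = (32, 32)
    nuc = circle_mask(shape, (16, 16), 5)
    ratio, _, _, reason = erk_activity(np.ones(shape), nuc, nuc.copy())
    assert np.isnan(ratio) and reason == "empty_cytoplasm"


def test_zero_nuclear_median_flagged():
    shape = (32, 32)
    nuc = circle_mask(shape, (16, 16), 4)
    cell = circle_mask(shape, (16, 16), 9)
    reporter = np.where(nuc, 0.0, 50.0)
    ratio, _, _, reason = erk_activity(reporter, nuc, cell)
    assert np.isnan(ratio) and reason == "zero_nuclear_median"


def test_noiseless_true_ratio_two_recovered(seg_params, morph_params):
    spec = noiseless(SceneSpec(image_height_px=256, image_width_px=256,
                               n_cells=1, rng_seed=2,
                               activity_ratio=(2.0, 0.0)))
    field, gt, *_ = generate_field(spec)
    nuclei = segment_nuclei(field.dna, seg_params)
    cells = segment_cells(field.reporter, nuclei, seg_params)
    df = records_to_frame(measure_field(field, nuclei, cells, seg_params,
                                        morph_params))
    assert len(df) == 1
    assert 1.9 <= df.loc[0, "erk_activity"] <= 2.1


def test_body_mask_disc_pixel_count():
    """Single-pixel nucleus dilated by the r=3 disc covers exactly its 29 px."""
    nuc = np.zeros((15, 15), dtype=bool)
    nuc[7, 7] = True
    body = cell_body_mask(nuc, 3)
    assert body.sum() == disk(3).sum() == 29


def test_body_mask_superset_and_clipping():
    nuc = np.zeros((20, 20), dtype=bool)
    nuc[0:3, 0:3] = True  # touching the corner: dilation clips, no error
    body = cell_body_mask(nuc, 4)
    assert (body | nuc).sum() == body.sum()
    assert body.shape == nuc.shape


def test_round_cell_fully_inside_body_has_zero_length(morph_params):
    shape = (64, 64)
    nuc = circle_mask(shape, (32, 32), 6)
    cell = circle_mask(shape, (32, 32), 8)
    body = cell_body_mask(nuc, 4)  # radius 10 covers the whole cell
    length, longest = process_length(np.where(cell, 200.0, 0.0), cell, body,
                                     morph_params, foreground=cell)
    assert length == 0.0 and longest == 0.0


def straight_process_scene(length=40, width=3):
    """Compact cell with one horizontal process anchored at the body edge."""
    shape = (128, 256)
    nuc = circle_mask(shape, (64, 60), 6)
    body = cell_body_mask(nuc, 4)
    proc = np.zeros(shape, dtype=bool)
    half = (width - 1) // 2
    c0 = 60 + 10  # body boundary
    proc[64 - half:64 + half + 1, c0:c0 + length + 1] = True
    cell = body | proc
    reporter = np.where(cell, 200.0, 0.0)
    return reporter, nuc, cell, body


def test_straight_40px_process_length(morph_params):
    reporter, nuc, cell, body = straight_process_scene(40)
    length, longest = process_length(reporter, cell, body, morph_params,
                                     foreground=cell)
    assert 32 <= length <= 44
    assert 32 <= longest <= 44


def test_length_monotone_in_true_length(morph_params):
    measured = []
    for true_len in (10, 40, 80):
        reporter, nuc, cell, body = straight_process_scene(true_len)
        length, _ = process_length(reporter, cell, body, morph_params,
                                   foreground=cell)
        measured.append(length)
    assert measured[0] < measured[1] < measured[2]


def test_weighted_mode_counts_diagonal_steps():
    shape = (64, 64)
    skel_src = np.zeros(shape, dtype=bool)
    idx = np.arange(10, 40)
    skel_src[idx, idx] = True  # 30-px diagonal line
    params = MorphologyParams(skeleton_length_mode="weighted")
    length, _ = process_length(np.ones(shape), skel_src,
                               np.zeros(shape, bool), params,
                               foreground=np.ones(shape, bool))
    assert length == pytest.approx(29 * np.sqrt(2), rel=0.05)


def test_measure_field_empty_maps(default_field, seg_params, morph_params):
    _, field, *_ = default_field
    empty = LabelMap(np.zeros(field.shape, dtype=np.int32), "nucleus")
    empty_c = LabelMap(np.zeros(field.shape, dtype=np.int32), "cell")
    assert measure_field(field, empty, empty_c, seg_params, morph_params) == []


def test_measure_field_cardinality_and_order(measured_field):
    # one record per cell label, ordered by cell id
    cells = measured_field[6]
    df = measured_field[-1]
    assert len(df) == cells.ids.size
    assert list(df["cell_id"]) == sorted(df["cell_id"])


def test_measure_field_integrity_error(default_field, seg_params, morph_params):
    _, field, *_ = default_field
    cell = np.zeros(field.shape, dtype=np.int32)
    cell[10:20, 10:20] = 1
    nuc = np.zeros(field.shape, dtype=np.int32)  # no nucleus for label 1
    with pytest.raises(IntegrityError):
        measure_field(field, LabelMap(nuc, "nucleus"), LabelMap(cell, "cell"),
                      seg_params, morph_params)


def test_activity_recovery_on_noisy_field(measured_field):
    """Known per-cell ratios are recovered through the full pipeline."""
    from scipy.stats import spearmanr
    _, field, gt, true_nuc, _, nuclei, _, df = measured_field
    paired = paired_measurements(gt, true_nuc, nuclei, df)
    rel_err = (paired["erk_activity"] - paired["true_activity_ratio"]).abs() \
        / paired["true_activity_ratio"]
    assert rel_err.median() < 0.10
    rho = spearmanr(paired["true_activity_ratio"],
                    paired["erk_activity"]).statistic
    assert rho > 0.95
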