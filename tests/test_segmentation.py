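"""Thresholding oracles and nucleus-seeded cell segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.filters import threshold_sauvola

from ktrquant import (LabelMap, SegmentationParams, otsu_threshold,
                      sauvola_binarize, segment_cells, segment_nuclei)
from ktrquant.benchmark import mask_iou, match_labels


def brute_force_otsu(counts, centers):
    """Exhaustive between-class variance search (independent oracle)."""
    best, best_t = -1.0, None
    total = counts.sum()
    for i in range(len(counts) - 1):
        if counts[i] == 0:
            continue  # same partition as the previous nonempty split
        w0 = counts[: i + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: i + 1] * centers[: i + 1]).sum() / w0
        mu1 = (counts[i + 1:] * centers[i + 1:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best:  # strict: ties keep the lowest threshold
            best, best_t = v, (centers[i] + centers[i + 1]) / 2.0
    return best_t


def naive_sauvola(image, window, k, R):
    """Double-loop Sauvola evaluation with mirror padding (oracle)."""
    r = window // 2
    padded = np.pad(image, r, mode="reflect")
    out = np.zeros(image.shape, dtype=bool)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            win = padded[i:i + window, j:j + window]
            m = win.mean()
            s = win.std()
            T = m * (1.0 + k * (s / R - 1.0))
            out[i, j] = image[i, j] > T
    return out


def test_otsu_perfectly_bimodal():
    counts = np.zeros(256)
    centers = np.arange(256, dtype=float)
    counts[10] = 50
    counts[200] = 50
    t = otsu_threshold(counts, centers)
    assert 10 < t < 200


def test_otsu_degenerate_single_bin(caplog):
    counts = np.zeros(16)
    counts[5] = 100
    centers = np.arange(16, dtype=float)
    assert otsu_threshold(counts, centers) == 5.0


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_otsu_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    nbins = int(rng.integers(2, 64))
    counts = rng.integers(0, 50, nbins).astype(float)
    if counts.sum() == 0:
        counts[0] = 1
    centers = np.sort(rng.uniform(0, 255, nbins))
    if np.count_nonzero(counts) < 2:
        return
    assert otsu_threshold(counts, centers) == brute_force_otsu(counts, centers)


@settings(max_examples=15, derandomize=True, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_sauvola_matches_naive_oracle(seed):
    rng = np.random.default_rng(seed)
    h, w = rng.integers(12, 40, 2)
    image = rng.uniform(0, 255, (h, w))
    window = int(rng.choice([3, 5, 9, 11]))
    k = float(rng.uniform(0.02, 0.5))
    got = sauvola_binarize(image, window, k, R=128.0)
    assert np.array_equal(got, naive_sauvola(image, window, k, 128.0))


def test_sauvola_constant_image_all_foreground():
    """Pinned convention: s=0 gives T = m(1-k) < m, so constant > T."""
    img = np.full((32, 32), 50.0)
    assert sauvola_binarize(img, 9, 0.1, R=128.0).all()


def test_sauvola_window_errors():
    img = np.zeros((16, 16))
    with pytest.raises(ValueError):
        sauvola_binarize(img, 4, 0.1)  # even window
    with pytest.raises(ValueError):
        sauvola_binarize(img, 33, 0.1)  # larger than image


def test_sauvola_agrees_with_skimage(rng):
    """Independent library cross-check of the local threshold map."""
    image = rng.uniform(0, 255, (64, 64))
    ours = sauvola_binarize(image, 15, 0.2, R=128.0)
    theirs = image > threshold_sauvola(image, window_size=15, k=0.2, r=128.0)
    assert (ours == theirs).mean() > 0.999


def test_segment_nuclei_recovers_ground_truth(segmented_field):
    _, field, gt, true_nuc, _, nuclei, _ = segmented_field
    match = match_labels(true_nuc.labels, nuclei.labels, iou_threshold=0.5)
    assert len(match) / len(gt) >= 0.95
    assert nuclei.ids.size <= len(gt) * 1.05


def test_blank_image_yields_no_nuclei(seg_params):
    out = segment_nuclei(np.zeros((128, 128)), seg_params)
    assert out.ids.size == 0


def test_min_area_filter_removes_small_nucleus(seg_params):
    img = np.zeros((64, 64))
    img[30:33, 30:33] = 300.0  # 9 px < min_area 50
    out = segment_nuclei(img, seg_params)
    assert out.ids.size == 0


def test_nucleus_labels_raster_order(seg_params):
    img = np.zeros((128, 128))
    img[80:95, 10:25] = 300.0   # lower-left, later in raster order
    img[10:25, 60:75] = 300.0   # upper-right, first in raster order
    out = segment_nuclei(img, seg_params)
    assert out.ids.size == 2
    first = np.argwhere(out.labels == 1)
    second = np.argwhere(out.labels == 2)
    assert first[:, 0].min() < second[:, 0].min()


def test_segment_cells_single_cell_jaccard(seg_params):
    from conftest import noiseless
    from ktrquant import SceneSpec, generate_field
    spec = SceneSpec(image_height_px=256, image_width_px=256, n_cells=1,
                     rng_seed=4)
    field, gt, true_nuc, true_cell = generate_field(spec)
    nuclei = segment_nuclei(field.dna, seg_params)
    cells = segment_cells(field.reporter, nuclei, seg_params)
    assert cells.ids.size == 1
    assert mask_iou(true_cell.labels == 1, cells.labels == cells.ids[0]) >= 0.8


def test_segment_cells_orphan_blob_discarded(seg_params):
    reporter = np.zeros((128, 128))
    reporter[20:40, 20:40] = 200.0   # cell with nucleus
    reporter[80:100, 80:100] = 200.0  # orphan blob, no nucleus
    nuc = np.zeros((128, 128), dtype=np.int32)
    nuc[27:33, 27:33] = 1
    cells = segment_cells(reporter, LabelMap(nuc, "nucleus"), seg_params)
    assert (cells.labels[80:100, 80:100] == 0).all()
    assert (cells.labels[20:40, 20:40] == 1).all()


def test_segment_cells_disjoint_equals_per_component(seg_params):
    reporter = np.zeros((128, 128))
    reporter[10:30, 10:30] = 200.0
    reporter[60:90, 60:90] = 200.0
    nuc = np.zeros((128, 128), dtype=np.int32)
    nuc[18:24, 18:24] = 1
    nuc[70:78, 70:78] = 2
    cells = segment_cells(reporter, LabelMap(nuc, "nucleus"), seg_params)
    assert (cells.labels[10:30, 10:30] == 1).all()
    assert (cells.labels[60:90, 60:90] == 2).all()


def test_segment_cells_geodesic_tie_goes_to_lower_label(seg_params):
    # one bright bar containing two nuclei: contested middle pixels at equal
    # geodesic distance must take the lower label
    reporter = np.zeros((64, 128))
    reporter[28:36, 10:110] = 200.0
    nuc = np.zeros((64, 128), dtype=np.int32)
    nuc[30:34, 20:28] = 1
    nuc[30:34, 92:100] = 2
    cells = segment_cells(reporter, LabelMap(nuc, "nucleus"), seg_params)
    assert set(np.unique(cells.labels)) == {0, 1, 2}
    # exact midpoint column belongs to label 1 (tie -> lower)
    mid_fg = (cells.labels[:, 59] > 0)
    assert (cells.labels[:, 59][mid_fg] == 1).all()
    # nucleus containment
    for k in (1, 2):
        assert not ((nuc == k) & (cells.labels != k)).any()


def test_nucleus_containment_on_default_field(segmented_field):
    *_, nuclei, cells = segmented_field
    for k in nuclei.ids:
        assert not ((nuclei.labels == k) & (cells.labels != k)).any()


def test_empty_nucleus_map_gives_empty_cells(seg_params, rng):
    reporter = rng.uniform(0, 100, (64, 64))
    empty = LabelMap(np.zeros((64, 64), dtype=np.int32), "nucleus")
    cells = segment_cells(reporter, empty, seg_params)
    assert not cells.labels.any()
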