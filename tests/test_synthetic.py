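"""Generator contracts: photometry, determinism, placement, noise model."""

import numpy as np
import pandas as pd
import pytest

from ktrquant import (PlacementError, SceneSpec, add_noise, generate_field,
                      render_processes)

from conftest import noiseless


class FixedRng:
    """Stub rng drawing fixed direction/length values."""

    def __init__(self, angle, length):
        self.angle = angle
        self.length = length

    def uniform(self, lo, hi, size=None):
        return self.angle

    def normal(self, mean, sd, size=None):
        return self.length


def test_empty_scene_is_background_only():
    spec = noiseless(SceneSpec(), n_cells=0)
    field, gt, nuc, cell = generate_field(spec)
    assert gt.empty
    assert not field.dna.any() and not field.reporter.any()
    assert not nuc.labels.any() and not cell.labels.any()


def test_noiseless_photometric_identity():
    """Mean cytoplasm / mean nucleus reporter intensity equals the true ratio."""
    spec = noiseless(SceneSpec(), n_cells=1, activity_ratio=(2.0, 0.0))
    field, gt, nuc, cell = generate_field(spec)
    nmask = nuc.labels == 1
    cyto = (cell.labels == 1) & ~nmask
    ratio = field.reporter[cyto].mean() / field.reporter[nmask].mean()
    assert ratio == pytest.approx(2.0, abs=1e-12)
    # photometric conservation: summed signal equals the per-cell budget
    total = field.reporter[cell.labels == 1].sum()
    assert total == pytest.approx(spec.total_reporter_per_cell, rel=1e-9)


def test_activity_ratio_encoding_across_cells():
    spec = noiseless(SceneSpec(), n_cells=20, rng_seed=5,
                     activity_ratio=(0.5, 3.0), activity_ratio_dist="uniform")
    field, gt, nuc, cell = generate_field(spec)
    for row in gt.itertuples():
        nmask = nuc.labels == row.cell_id
        cyto = (cell.labels == row.cell_id) & ~nmask
        ratio = field.reporter[cyto].mean() / field.reporter[nmask].mean()
        assert ratio == pytest.approx(row.true_activity_ratio, rel=0.01)


def test_seed_determinism():
    spec = SceneSpec(n_cells=50, rng_seed=7)
    a = generate_field(spec)
    b = generate_field(spec)
    assert np.array_equal(a[0].dna, b[0].dna)
    assert np.array_equal(a[0].reporter, b[0].reporter)
    pd.testing.assert_frame_equal(a[1], b[1])
    assert np.array_equal(a[2].labels, b[2].labels)
    assert np.array_equal(a[3].labels, b[3].labels)


def test_ground_truth_ids_consistent(default_field):
    _, field, gt, nuc, cell = default_field
    assert gt["cell_id"].is_unique and (gt["cell_id"] > 0).all()
    assert set(np.unique(nuc.labels[nuc.labels > 0])) == set(gt["cell_id"])
    assert set(np.unique(cell.labels[cell.labels > 0])) == set(gt["cell_id"])
    # nucleus_k contained in cell_k
    for k in gt["cell_id"]:
        assert not ((nuc.labels == k) & (cell.labels != k)).any()
    assert (gt["true_activity_ratio"] > 0).all()
    assert (gt["true_process_length_px"] >= 0).all()


def test_placement_failure_names_achieved_count():
    spec = SceneSpec(image_height_px=120, image_width_px=120, n_cells=40,
                     max_placement_attempts=30, rng_seed=0)
    with pytest.raises(PlacementError) as exc:
        generate_field(spec)
    assert exc.value.requested == 40
    assert 0 <= exc.value.achieved < 40
    assert str(exc.value.achieved) in str(exc.value)


def test_add_noise_identity(rng):
    img = rng.uniform(0, 100, (32, 32))
    out = add_noise(img, 0.0, 0.0, False, rng)
    assert np.array_equal(out, img)


def test_add_noise_gaussian_moment(rng):
    img = np.full((100, 100), 100.0)
    out = add_noise(img, 0.0, 5.0, False, rng)
    assert 4.5 <= out.std(ddof=1) <= 5.5


def test_add_noise_poisson_moment(rng):
    img = np.full((100, 100), 50.0)
    out = add_noise(img, 0.0, 0.0, True, rng)
    se = np.sqrt(50.0 / img.size)
    assert abs(out.mean() - 50.0) <= 3 * se


def test_add_noise_nonnegative_and_errors(rng):
    img = np.zeros((50, 50))
    out = add_noise(img, 0.0, 10.0, False, rng)
    assert out.min() >= 0
    with pytest.raises(ValueError):
        add_noise(img, -1.0, 0.0, False, rng)
    with pytest.raises(ValueError):
        add_noise(img, 0.0, -1.0, False, rng)


def test_render_processes_empty(rng):
    mask, total, lengths = render_processes((64, 64), (32, 32), 0,
                                            (20.0, 5.0), 3, rng)
    assert not mask.any() and total == 0.0 and lengths.size == 0


def test_render_processes_axis_aligned_path():
    """A horizontal 40-px process of width 3 covers a 3x41 pixel bar."""
    rng = FixedRng(angle=0.0, length=40.0)  # angle 0 -> +col direction
    mask, total, lengths = render_processes((64, 128), (32, 20), 1,
                                            (40.0, 0.0), 3, rng)
    assert total == 40.0
    rows = np.unique(np.nonzero(mask)[0])
    assert np.array_equal(rows, [31, 32, 33])
    # off-center rows carry the undilated 41-px path (caps round the center row)
    cols = np.nonzero(mask[31])[0]
    assert cols.max() - cols.min() == 40


def test_render_processes_resample_oracle():
    """Total true length equals lengths re-sampled from the same seed."""
    seed, n, params = 99, 3, (25.0, 8.0)
    rng = np.random.default_rng(seed)
    _, total, _ = render_processes((256, 256), (128, 128), n, params, 3, rng)
    oracle = np.random.default_rng(seed)
    expect = 0.0
    for _ in range(n):
        oracle.uniform(0.0, 2.0 * np.pi)  # direction draw
        expect += float(np.clip(oracle.normal(*params), 0.0,
                                params[0] + 3 * params[1]))
    assert total == pytest.approx(expect, abs=1e-12)


def test_spec_validation_errors():
    with pytest.raises(ValueError):
        SceneSpec(n_cells=-1)
    with pytest.raises(ValueError):
        SceneSpec(nucleus_radius_px=(0.0, 5.0))
    with pytest.raises(ValueError):
        SceneSpec(activity_ratio=(-1.0, 0.2))
    with pytest.raises(ValueError):
        SceneSpec(gaussian_noise_sd=-0.5)
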