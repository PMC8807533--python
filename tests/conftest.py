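import numpy as np
import pytest

from ktrquant import (SceneSpec, SegmentationParams, MorphologyParams,
                      generate_field, segment_nuclei, segment_cells)
from ktrquant.quantify import measure_field, records_to_frame


@pytest.fixture(scope="session")
def seg_params():
    return SegmentationParams()


@pytest.fixture(scope="session")
def morph_params():
    return MorphologyParams()


@pytest.fixture(scope="session")
def default_field():
    """One default-noise synthetic field with ground truth."""
    spec = SceneSpec(rng_seed=3)
    return (spec,) + generate_field(spec)


@pytest.fixture(scope="session")
def segmented_field(default_field, seg_params):
    """Default field run through nucleus and cell segmentation."""
    spec, field, gt, true_nuc, true_cell = default_field
    nuclei = segment_nuclei(field.dna, seg_params)
    cells = segment_cells(field.reporter, nuclei, seg_params)
    return spec, field, gt, true_nuc, true_cell, nuclei, cells


@pytest.fixture(scope="session")
def measured_field(segmented_field, seg_params, morph_params):
    """Per-cell records of the default field."""
    spec, field, gt, true_nuc, true_cell, nuclei, cells = segmented_field
    records = measure_field(field, nuclei, cells, seg_params, morph_params)
    return segmented_field + (records_to_frame(records),)


def noiseless(spec: SceneSpec, **kwargs) -> SceneSpec:
    return spec.replace(background_level=0.0, gaussian_noise_sd=0.0,
                        poisson_noise=False, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
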