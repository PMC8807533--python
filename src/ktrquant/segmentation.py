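"""Nucleus and cell segmentation for two-channel KTR fields.

Nuclei are found on the DNA channel by Gaussian smoothing, a global Otsu
threshold on the intensity histogram, hole filling and an area gate. Cell
boundaries are found on the reporter channel with a local Sauvola
threshold; every foreground pixel is then assigned to the nearest nucleus
by geodesic (within-foreground) distance, so each nucleus seeds exactly
one cell and foreground blobs containing no nucleus are discarded.

Conventions pinned throughout: strict ``>`` comparison against thresholds,
mirror padding for window statistics, 8-connectivity for components, ties
in the geodesic assignment go to the lower label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .containers import CONNECTIVITY_8, LabelMap

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "otsu_threshold",
    "segment_nuclei",
    "sauvola_binarize",
    "segment_cells",
]


@dataclass
class SegmentationParams:
    """Free parameters of the thresholding protocol.

    The thresholding algorithms themselves are fixed (Otsu for nuclei,
    Sauvola for the cell boundary); these are the knobs a protocol would
    tune per cell type. ``sauvola_R`` defaults to half the dynamic range:
    half the dtype range for integer images, half the image maximum for
    float images.
    """

    nucleus_smoothing_sigma: float = 1.0
    nucleus_min_area: int = 50
    nucleus_max_area: int = 5000
    sauvola_window_px: int = 25
    sauvola_k: float = 0.1
    sauvola_R: float | None = None
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.sauvola_window_px < 3 or self.sauvola_window_px % 2 == 0:
            raise ValueError("sauvola_window_px must be odd and >= 3")
        if self.nucleus_min_area >= self.nucleus_max_area:
            raise ValueError("nucleus_min_area must be < nucleus_max_area")


def otsu_threshold(counts: np.ndarray, bin_centers: np.ndarray) -> float:
    """Global threshold maximizing between-class variance of a histogram.

    Candidate splits separate the histogram after each nonempty bin
    (splitting after an empty bin yields the same partition as splitting
    after the previous nonempty bin, so those duplicates are excluded and
    the lowest-threshold tie-break stays well defined); the returned
    threshold is the midpoint between the two bin centers flanking the best
    split, so it falls strictly between the classes. A pixel is foreground
    iff its value is strictly greater than the threshold. Ties are broken
    toward the lowest qualifying threshold. A histogram with all mass in
    one bin is degenerate: that bin's center is returned (and logged), so
    strict-greater comparison yields an empty foreground.
    """
    counts = np.asarray(counts, dtype=float)
    bin_centers = np.asarray(bin_centers, dtype=float)
    if counts.ndim != 1 or counts.shape != bin_centers.shape:
        raise ValueError("counts and bin_centers must be equal-length 1-D")
    if counts.sum() <= 0:
        raise ValueError("histogram must have at least one nonempty bin")
    nonzero = np.nonzero(counts)[0]
    if nonzero.size == 1:
        logger.warning("degenerate histogram: all mass in one bin")
        return float(bin_centers[nonzero[0]])

    # split after bin i: class0 = bins[0..i], class1 = bins[i+1..]
    w0 = np.cumsum(counts)[:-1]
    w1 = counts.sum() - w0
    csum = np.cumsum(counts * bin_centers)[:-1]
    total = (counts * bin_centers).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum / w0
        mu1 = (total - csum) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    valid = (w0 > 0) & (w1 > 0) & (counts[:-1] > 0)
    var_between = np.where(valid, var_between, -np.inf)
    i = int(np.argmax(var_between))
    return float((bin_centers[i] + bin_centers[i + 1]) / 2.0)


def _relabel_raster_order(mask_labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels consecutively by first pixel in raster order."""
    out = np.zeros_like(mask_labels, dtype=np.int32)
    flat = mask_labels.ravel()
    order = []
    seen = set()
    for v in flat[flat > 0]:
        if v not in seen:
            seen.add(v)
            order.append(v)
    for new, old in enumerate(order, start=1):
        out[mask_labels == old] = new
    return out


def segment_nuclei(dna: np.ndarray, params: SegmentationParams) -> LabelMap:
    """Segment nuclei from the DNA-stain channel.

    Pipeline: Gaussian smooth -> global Otsu over a 256-bin histogram ->
    strict-greater binarization -> optional hole filling -> 8-connected
    components -> discard components with area outside
    ``[nucleus_min_area, nucleus_max_area]``. Labels are assigned in
    raster-scan order of each component's first pixel. An empty foreground
    is a valid (logged) outcome, not an error.
    """
    dna = np.asarray(dna, dtype=float)
    smooth = ndi.gaussian_filter(dna, params.nucleus_smoothing_sigma,
                                 mode="mirror")
    counts, edges = np.histogram(smooth, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2.0
    t = otsu_threshold(counts, centers)
    mask = smooth > t
    if params.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask, structure=CONNECTIVITY_8)
    if n == 0:
        logger.info("no nuclei found (empty foreground)")
        return LabelMap(labels.astype(np.int32), "nucleus")
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    bad = np.nonzero((areas < params.nucleus_min_area)
                     | (areas > params.nucleus_max_area))[0] + 1
    if bad.size:
        labels[np.isin(labels, bad)] = 0
    return LabelMap(_relabel_raster_order(labels), "nucleus")


def sauvola_binarize(
    image: np.ndarray,
    window_px: int = 25,
    k: float = 0.1,
    R: float | None = None,
) -> np.ndarray:
    """Local Sauvola binarization of an intensity image.

    Per pixel the threshold is ``T = m * (1 + k * (s/R - 1))`` where ``m``
    and ``s`` are the mean and standard deviation over the centered
    ``window_px`` square (mirror-padded at edges); a pixel is foreground
    iff its intensity is strictly greater than ``T``. Note the pinned
    convention that a constant image with ``k > 0`` is all-foreground
    (``s = 0`` gives ``T = m (1 - k) < m``).
    """
    image = np.asarray(image, dtype=float)
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window_px > min(image.shape):
        raise ValueError(
            f"window {window_px} larger than image {image.shape}")
    if R is None:
        R = _default_sauvola_R(image)
    m = ndi.uniform_filter(image, size=window_px, mode="mirror")
    m2 = ndi.uniform_filter(image * image, size=window_px, mode="mirror")
    s = np.sqrt(np.clip(m2 - m * m, 0.0, None))
    T = m * (1.0 + k * (s / R - 1.0))
    return image > T


def _default_sauvola_R(image: np.ndarray) -> float:
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return (info.max - info.min) / 2.0
    mx = float(image.max()) if image.size else 0.0
    return mx / 2.0 if mx > 0 else 0.5


def segment_cells(
    reporter: np.ndarray,
    nuclei: LabelMap,
    params: SegmentationParams,
) -> LabelMap:
    """Assign reporter foreground to cells seeded by nucleus positions.

    Foreground is the union of the Sauvola mask and the nucleus pixels.
    Each foreground pixel receives the label of the nucleus reachable by
    the shortest within-foreground (geodesic, 8-connected) path; equal
    distances go to the lower label. Foreground components containing no
    nucleus are discarded, and nucleus_k is contained in cell_k for every
    label by construction.
    """
    reporter = np.asarray(reporter, dtype=float)
    if reporter.shape != nuclei.labels.shape:
        raise ValueError("reporter and nucleus map shapes differ")
    cell = np.zeros_like(nuclei.labels, dtype=np.int32)
    if nuclei.ids.size == 0:
        logger.info("empty nucleus map: empty cell map")
        return LabelMap(cell, "cell")
    fg = sauvola_binarize(reporter, params.sauvola_window_px,
                          params.sauvola_k, params.sauvola_R)
    fg |= nuclei.labels > 0
    comps, ncomp = ndi.label(fg, structure=CONNECTIVITY_8)
    if ncomp == 0:
        return LabelMap(cell, "cell")
    # which nuclei sit in which foreground component
    objects = ndi.find_objects(comps)
    for ci in range(1, ncomp + 1):
        sl = objects[ci - 1]
        comp_mask = comps[sl] == ci
        nuc_here = np.unique(nuclei.labels[sl][comp_mask])
        nuc_here = nuc_here[nuc_here > 0]
        if nuc_here.size == 0:
            continue  # orphan blob: discarded
        if nuc_here.size == 1:
            cell[sl][comp_mask] = int(nuc_here[0])
            continue
        cell[sl][comp_mask] = _geodesic_assign(
            comp_mask, np.where(comp_mask, nuclei.labels[sl], 0))[comp_mask]
    return LabelMap(cell, "cell")


_INF = np.iinfo(np.int32).max


def _geodesic_assign(fg: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Multi-source 8-connected BFS label growth within ``fg``.

    Pixels claimed at the same BFS depth by several labels take the lowest
    label (min over the 8-neighborhood each round).
    """
    lab = np.where(seeds > 0, seeds.astype(np.int64), 0)
    grow = fg & (lab == 0)
    sentinel = np.where(lab > 0, lab, _INF)
    while True:
        cand = ndi.minimum_filter(sentinel, size=3, mode="constant", cval=_INF)
        newly = grow & (cand < _INF)
        if not newly.any():
            break
        lab[newly] = cand[newly]
        sentinel[newly] = cand[newly]
        grow &= ~newly
    return lab.astype(np.int32)
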