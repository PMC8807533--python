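"""Synthetic two-channel fluorescence fields of KTR-reporter cells.

The generator emulates the statistical structure the measurement pipeline
assumes: each cell has an elliptical nucleus (DNA channel), an elliptical
cytoplasm body, and a few thin elongated processes, with the reporter
partitioned between nucleus and cytoplasm according to a known per-cell
activity ratio (cytoplasm/nucleus mean intensity). Because fills are
uniform, the median-based readout of the measurement stage coincides with
the generative mean, so recovery tolerances are interpretable.

Every field carries a ground-truth table (one row per rendered cell) plus
paired nucleus/cell label maps, enabling segmentation- and
parameter-recovery tests against known truth.

Coordinates are 0-based ``(row, col)``; all dimensions are pixels.
Intensities are nonnegative counts (16-bit on export).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .containers import FieldImage, LabelMap

__all__ = [
    "SceneSpec",
    "PlacementError",
    "CONDITION_PRESETS",
    "scene_for_condition",
    "add_noise",
    "render_processes",
    "generate_field",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping cell placement fails.

    Carries how many cells were achieved before giving up.
    """

    def __init__(self, requested: int, achieved: int, attempts: int):
        self.requested = requested
        self.achieved = achieved
        self.attempts = attempts
        super().__init__(
            f"placed only {achieved}/{requested} non-overlapping cells "
            f"after {attempts} attempts per cell; reduce n_cells or enlarge "
            f"the field"
        )


@dataclass
class SceneSpec:
    """Parameters of one synthetic field.

    Distribution parameters are ``(mean, sd)`` pairs when the matching
    ``*_dist`` is ``"normal"`` (values clipped to ``[0, mean + 3 sd]``) and
    ``(low, high)`` pairs when it is ``"uniform"``.

    Identical spec + seed produce bit-identical images and ground truth.
    """

    image_height_px: int = 768
    image_width_px: int = 768
    n_cells: int = 55
    nucleus_radius_px: tuple[float, float] = (5.0, 7.0)
    cytoplasm_radius_px: tuple[float, float] = (9.0, 13.0)
    n_processes_per_cell: tuple[int, int] = (1, 3)
    process_length_px: tuple[float, float] = (12.0, 5.0)
    process_length_dist: str = "normal"
    process_width_px: int = 3
    activity_ratio: tuple[float, float] = (1.8, 0.3)
    activity_ratio_dist: str = "normal"
    total_reporter_per_cell: float = 150_000.0
    dna_intensity: float = 300.0
    background_level: float = 0.0
    gaussian_noise_sd: float = 3.0
    poisson_noise: bool = True
    allow_border_clipping: bool = False
    rng_seed: int = 0
    max_placement_attempts: int = 500

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("nucleus_radius_px", "cytoplasm_radius_px"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be an ordered pair of positive lengths")
        lo, hi = self.n_processes_per_cell
        if lo < 0 or hi < lo:
            raise ValueError("n_processes_per_cell must be an ordered pair >= 0")
        if self.process_width_px < 1:
            raise ValueError("process_width_px must be >= 1")
        for name in ("activity_ratio_dist", "process_length_dist"):
            if getattr(self, name) not in ("normal", "uniform"):
                raise ValueError(f"{name} must be 'normal' or 'uniform'")
        if self.activity_ratio_dist == "normal" and self.activity_ratio[0] <= 0:
            raise ValueError("activity_ratio mean must be > 0")
        if self.activity_ratio_dist == "uniform" and self.activity_ratio[0] <= 0:
            raise ValueError("activity_ratio lower bound must be > 0")
        if self.total_reporter_per_cell <= 0 or self.dna_intensity <= 0:
            raise ValueError("photon-count scales must be > 0")
        if self.background_level < 0 or self.gaussian_noise_sd < 0:
            raise ValueError("background and noise sd must be >= 0")

    def replace(self, **kwargs) -> "SceneSpec":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# Study-condition presets: a high-activity control arm with short processes
# versus an ERK-inhibitor-like arm with nuclear-shifted reporter (ratio < 1)
# and elongated processes, mimicking the differentiation phenotype.
CONDITION_PRESETS: dict[str, dict] = {
    "control": {"activity_ratio": (1.8, 0.3), "process_length_px": (12.0, 5.0)},
    "atra": {"activity_ratio": (1.3, 0.3), "process_length_px": (16.0, 6.0)},
    "inhibitor": {"activity_ratio": (0.9, 0.2), "process_length_px": (30.0, 8.0)},
}


def scene_for_condition(base: SceneSpec, preset: str, **overrides) -> SceneSpec:
    """Apply a named condition preset (plus overrides) to a base spec."""
    if preset not in CONDITION_PRESETS:
        raise KeyError(f"unknown condition preset {preset!r}; "
                       f"have {sorted(CONDITION_PRESETS)}")
    params = dict(CONDITION_PRESETS[preset])
    params.update(overrides)
    return base.replace(**params)


def add_noise(
    image: np.ndarray,
    background_level: float,
    gaussian_sd: float,
    poisson: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply background offset, shot noise and read noise to an image.

    The model is ``Poisson(image + background) + N(0, sd)``, clipped at 0.
    With background 0 and both noise sources disabled the input is returned
    unchanged (as a copy).
    """
    image = np.asarray(image, dtype=float)
    if image.size and image.min() < 0:
        raise ValueError("input image must be nonnegative")
    if background_level < 0:
        raise ValueError("background_level must be >= 0")
    if gaussian_sd < 0:
        raise ValueError("gaussian_sd must be >= 0")
    out = image + background_level
    if poisson:
        out = rng.poisson(out).astype(float)
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def _sample(params: tuple[float, float], dist: str, rng: np.random.Generator,
            size=None):
    lo_or_mean, hi_or_sd = params
    if dist == "uniform":
        return rng.uniform(lo_or_mean, hi_or_sd, size=size)
    draw = rng.normal(lo_or_mean, hi_or_sd, size=size)
    return np.clip(draw, 0.0, lo_or_mean + 3.0 * hi_or_sd)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  a: float, b: float, theta: float) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_processes(
    shape: tuple[int, int],
    center: tuple[float, float],
    n_processes: int,
    length_params: tuple[float, float],
    width_px: int,
    rng: np.random.Generator,
    anchor_radius: float | Callable[[float], float] = 0.0,
    length_dist: str = "normal",
) -> tuple[np.ndarray, float, np.ndarray]:
    """Render thin cell processes as thickened straight pixel paths.

    Each process is drawn from a point on the cell-body boundary
    (``anchor_radius`` away from ``center`` along a uniform random
    direction, minus 1 px so the path stays 8-connected to the body)
    outward for a sampled length, then dilated to ``width_px``. Per
    process the rng draws, in order, a direction ``U(0, 2*pi)`` and a
    length from ``length_params``.

    Returns the boolean mask, the true total length (sum of the sampled
    path lengths, in px), and the per-process lengths.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    mask = np.zeros(shape, dtype=bool)
    lengths = np.zeros(n_processes, dtype=float)
    for j in range(n_processes):
        angle = rng.uniform(0.0, 2.0 * np.pi)
        length = float(_sample(length_params, length_dist, rng))
        lengths[j] = max(length, 0.0)
        if lengths[j] <= 0:
            continue
        r_anchor = anchor_radius(angle) if callable(anchor_radius) else anchor_radius
        r_anchor = max(r_anchor - 1.0, 0.0)
        u = np.array([np.sin(angle), np.cos(angle)])  # (row, col) direction
        start = np.asarray(center) + r_anchor * u
        end = start + lengths[j] * u
        rr, cc = draw_line(int(round(start[0])), int(round(start[1])),
                           int(round(end[0])), int(round(end[1])))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[keep], cc[keep]] = True
    if mask.any() and width_px > 1:
        mask = ndi.binary_dilation(mask, structure=disk((width_px - 1) // 2))
    return mask, float(lengths.sum()), lengths


_GT_COLUMNS = [
    "cell_id", "centroid_row", "centroid_col", "true_activity_ratio",
    "true_process_length_px", "nucleus_area_px2", "cell_area_px2",
    "touches_border",
]


def generate_field(
    spec: SceneSpec,
    field_id: str = "field_0",
    condition: str = "",
) -> tuple[FieldImage, pd.DataFrame, LabelMap, LabelMap]:
    """Generate one synthetic field with ground truth and label maps.

    Cells are placed by rejection sampling so that rendered masks of
    distinct cells never touch (a 2-px clearance is enforced); the
    measurement pipeline has no declumping stage, so overlap is disallowed.
    Before noise, the mean reporter intensity over a cell's cytoplasm
    divided by the mean over its nucleus equals that cell's
    ``true_activity_ratio`` exactly, and the summed reporter signal per
    cell equals ``total_reporter_per_cell``.

    Returns ``(FieldImage, ground_truth, nucleus LabelMap, cell LabelMap)``.
    Raises :class:`PlacementError` if the field cannot hold ``n_cells``
    non-overlapping cells within the attempt budget.
    """
    rng = np.random.default_rng(spec.rng_seed)
    H, W = spec.image_height_px, spec.image_width_px
    dna = np.zeros((H, W), dtype=float)
    reporter = np.zeros((H, W), dtype=float)
    nuc_lab = np.zeros((H, W), dtype=np.int32)
    cell_lab = np.zeros((H, W), dtype=np.int32)
    # occupancy holds already-placed masks dilated by 2 px, so a candidate
    # that avoids it keeps a >= 2 px gap to every neighbor
    occupancy = np.zeros((H, W), dtype=bool)
    clearance = disk(2)

    mean_len, sd_len = spec.process_length_px
    if spec.process_length_dist == "normal":
        max_len = mean_len + 3.0 * sd_len
    else:
        max_len = sd_len  # (low, high) pair

    rows = []
    for i in range(1, spec.n_cells + 1):
        # geometry draws happen once per cell, before placement attempts,
        # so shapes are seed-stable regardless of how placement goes
        a_n = float(rng.uniform(*spec.nucleus_radius_px))
        b_n = float(rng.uniform(*spec.nucleus_radius_px))
        theta = float(rng.uniform(0.0, np.pi))
        a_c = max(float(rng.uniform(*spec.cytoplasm_radius_px)), a_n + 2.0)
        b_c = max(float(rng.uniform(*spec.cytoplasm_radius_px)), b_n + 2.0)
        ratio = float(_sample(spec.activity_ratio, spec.activity_ratio_dist, rng))
        ratio = max(ratio, 0.05)
        lo_p, hi_p = spec.n_processes_per_cell
        n_proc = int(rng.integers(lo_p, hi_p + 1))

        extent = int(np.ceil(max(a_c, b_c) + (max_len if n_proc else 0.0)
                             + spec.process_width_px + 2))
        side = 2 * extent + 1
        c_local = (float(extent), float(extent))
        nucleus_local = _ellipse_mask((side, side), c_local, a_n, b_n, theta)

        def boundary_radius(angle: float, _a=a_c, _b=b_c, _t=theta) -> float:
            psi = angle - _t
            return 1.0 / np.hypot(np.cos(psi) / _a, np.sin(psi) / _b)

        body_local = _ellipse_mask((side, side), c_local, a_c, b_c, theta)
        proc_local, true_len, _ = render_processes(
            (side, side), c_local, n_proc, spec.process_length_px,
            spec.process_width_px, rng, anchor_radius=boundary_radius,
            length_dist=spec.process_length_dist,
        )
        cell_local = nucleus_local | body_local | proc_local

        placed = False
        for _ in range(spec.max_placement_attempts):
            if spec.allow_border_clipping:
                cy = int(rng.integers(0, H))
                cx = int(rng.integers(0, W))
            else:
                if H - extent <= extent or W - extent <= extent:
                    raise PlacementError(spec.n_cells, i - 1,
                                         spec.max_placement_attempts)
                cy = int(rng.integers(extent, H - extent))
                cx = int(rng.integers(extent, W - extent))
            r0, r1 = cy - extent, cy + extent + 1
            c0, c1 = cx - extent, cx + extent + 1
            lr0, lc0 = max(0, -r0), max(0, -c0)
            lr1 = side - max(0, r1 - H)
            lc1 = side - max(0, c1 - W)
            gr0, gc0 = max(r0, 0), max(c0, 0)
            gr1, gc1 = min(r1, H), min(c1, W)
            nuc_crop = nucleus_local[lr0:lr1, lc0:lc1]
            cell_crop = cell_local[lr0:lr1, lc0:lc1]
            if not nuc_crop.any():
                continue  # nucleus clipped away entirely
            if (occupancy[gr0:gr1, gc0:gc1] & cell_crop).any():
                continue
            placed = True
            break
        if not placed:
            raise PlacementError(spec.n_cells, i - 1, spec.max_placement_attempts)

        view = (slice(gr0, gr1), slice(gc0, gc1))
        nuc_lab[view][nuc_crop] = i
        cell_lab[view][cell_crop] = i
        occ_crop = ndi.binary_dilation(cell_crop, structure=clearance)
        occupancy[view] |= occ_crop

        # photometry: uniform fills whose cytoplasm/nucleus mean equals ratio
        cyto_crop = cell_crop & ~nuc_crop
        area_n = int(nuc_crop.sum())
        area_cell = int(cell_crop.sum())
        area_cyto = area_cell - area_n
        i_nuc = spec.total_reporter_per_cell / (area_n + ratio * area_cyto)
        reporter[view][nuc_crop] = i_nuc
        reporter[view][cyto_crop] = ratio * i_nuc
        dna[view][nuc_crop] = spec.dna_intensity

        rr, cc = np.nonzero(cell_crop)
        touches = bool(gr0 == 0 and (rr + gr0 == 0).any()
                       or gr1 == H and (rr + gr0 == H - 1).any()
                       or gc0 == 0 and (cc + gc0 == 0).any()
                       or gc1 == W and (cc + gc0 == W - 1).any())
        rows.append({
            "cell_id": i,
            "centroid_row": float(rr.mean() + gr0),
            "centroid_col": float(cc.mean() + gc0),
            "true_activity_ratio": ratio,
            "true_process_length_px": true_len,
            "nucleus_area_px2": area_n,
            "cell_area_px2": area_cell,
            "touches_border": touches,
        })

    reporter = add_noise(reporter, spec.background_level,
                         spec.gaussian_noise_sd, spec.poisson_noise, rng)
    dna = add_noise(dna, spec.background_level,
                    spec.gaussian_noise_sd, spec.poisson_noise, rng)

    gt = pd.DataFrame(rows, columns=_GT_COLUMNS)
    field = FieldImage(dna=dna, reporter=reporter, field_id=field_id,
                       condition=condition)
    return field, gt, LabelMap(nuc_lab, "nucleus"), LabelMap(cell_lab, "cell")
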