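"""Shared in-memory containers for imaging fields and segmentation masks.

A :class:`FieldImage` holds one two-channel microscopy field: a DNA-stain
channel (Hoechst; nuclei) and a kinase-translocation-reporter fluorescence
channel, pixel-registered on the same grid. A :class:`LabelMap` is an
integer-labeled mask (0 = background) aligned to such a field, either for
nuclei or for whole cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = ["FieldImage", "LabelMap"]


@dataclass
class FieldImage:
    """One imaging field: two co-registered 2-D intensity channels.

    Parameters
    ----------
    dna : ndarray
        DNA-stain channel (nuclei), nonnegative finite intensities.
    reporter : ndarray
        KTR reporter channel, same shape as ``dna``.
    field_id : str
        Identifier of the field within a run.
    condition : str
        Treatment label (e.g. ``DMSO``, ``ATRA``, ``SCH``).
    """

    dna: np.ndarray
    reporter: np.ndarray
    field_id: str = "field_0"
    condition: str = ""

    def __post_init__(self) -> None:
        self.dna = np.asarray(self.dna, dtype=float)
        self.reporter = np.asarray(self.reporter, dtype=float)
        if self.dna.ndim != 2 or self.reporter.ndim != 2:
            raise ValueError("channels must be 2-D arrays")
        if self.dna.shape != self.reporter.shape:
            raise ValueError(
                f"channel shapes differ: dna {self.dna.shape} vs "
                f"reporter {self.reporter.shape}"
            )
        for name, chan in (("dna", self.dna), ("reporter", self.reporter)):
            if not np.all(np.isfinite(chan)):
                raise ValueError(f"{name} channel contains non-finite values")
            if chan.size and chan.min() < 0:
                raise ValueError(f"{name} channel contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dna.shape


# 8-connectivity used everywhere a connected component is formed
CONNECTIVITY_8 = np.ones((3, 3), dtype=bool)


@dataclass
class LabelMap:
    """Integer-labeled segmentation mask (0 = background, k > 0 = object k)."""

    labels: np.ndarray
    kind: str = "nucleus"  # "nucleus" | "cell"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer typed")
        if self.kind not in ("nucleus", "cell"):
            raise ValueError(f"unknown label-map kind {self.kind!r}")

    @property
    def ids(self) -> np.ndarray:
        """Sorted positive labels present in the map."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def check_connected(self) -> bool:
        """True if every positive label forms one 8-connected component."""
        for k in self.ids:
            _, n = ndi.label(self.labels == k, structure=CONNECTIVITY_8)
            if n != 1:
                return False
        return True
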