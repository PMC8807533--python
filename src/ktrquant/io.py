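"""TIFF / CSV / YAML input-output helpers.

Fields are stored as 2-page 16-bit grayscale TIFFs (page 0 = DNA, page 1 =
reporter); label maps as 16-bit single-page TIFFs. Intensities are rounded
and clipped to the 16-bit range on export; in-memory processing stays in
float.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import FieldImage, LabelMap
from .synthetic import SceneSpec

__all__ = [
    "write_field_tiff", "read_field_tiff",
    "write_labelmap_tiff", "read_labelmap_tiff",
    "write_scene_yaml", "read_scene_yaml",
    "load_yaml", "dump_yaml",
]


def _to_uint16(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(arr), 0, 65535).astype(np.uint16)


def write_field_tiff(path: str | Path, field: FieldImage) -> None:
    stack = np.stack([_to_uint16(field.dna), _to_uint16(field.reporter)])
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_field_tiff(path: str | Path, field_id: str = "",
                    condition: str = "") -> FieldImage:
    stack = tifffile.imread(str(path))
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"{path}: expected a 2-page grayscale TIFF, "
                         f"got shape {stack.shape}")
    return FieldImage(dna=stack[0].astype(float),
                      reporter=stack[1].astype(float),
                      field_id=field_id or Path(path).stem,
                      condition=condition)


def write_labelmap_tiff(path: str | Path, labelmap: LabelMap) -> None:
    if labelmap.labels.max(initial=0) > 65535:
        raise ValueError("more than 65535 labels cannot be stored as uint16")
    tifffile.imwrite(str(path), labelmap.labels.astype(np.uint16),
                     photometric="minisblack")


def read_labelmap_tiff(path: str | Path, kind: str) -> LabelMap:
    return LabelMap(tifffile.imread(str(path)).astype(np.int32), kind)


def write_scene_yaml(path: str | Path, spec: SceneSpec) -> None:
    dump_yaml(path, spec.to_dict())


def read_scene_yaml(path: str | Path) -> SceneSpec:
    data = load_yaml(path)
    data = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return SceneSpec(**data)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(path: str | Path, data: dict) -> None:
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_clean(data), fh, sort_keys=False)


def frame_to_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
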