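"""Segment the simulated fields and measure every cell.

Reads the TIFFs written by 01_simulate_fields.py, runs Otsu nucleus
segmentation, Sauvola + geodesic cell assignment, and the per-cell
measurements (C/N activity ratio, process length), and writes
scratch/run_main/cells.csv.
"""

from pathlib import Path

import pandas as pd

from ktrquant.io import frame_to_csv, read_field_tiff
from ktrquant.pipeline import process_fields
from ktrquant.quantify import MorphologyParams
from ktrquant.segmentation import SegmentationParams

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "run_main"


def main() -> None:
    index = pd.read_csv(RUN_DIR / "fields_index.csv")
    fields = [read_field_tiff(RUN_DIR / row.path, field_id=row.field_id,
                              condition=row.condition)
              for row in index.itertuples()]
    cells, _ = process_fields(fields, SegmentationParams(), MorphologyParams())
    frame_to_csv(cells, RUN_DIR / "cells.csv")
    print(f"measured {len(cells)} cells across {len(fields)} fields")
    print(cells.groupby("condition")[["erk_activity", "process_length_px"]]
          .median().round(3))


if __name__ == "__main__":
    main()
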