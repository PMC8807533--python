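"""Apply quality control to the per-cell measurements.

Geometry gates (border, area, nucleus fraction) plus a per-condition
Tukey-IQR outlier rule on activity and length. Flags are reversible;
nothing is deleted. Writes scratch/run_main/cells_qc.csv and the compact
per-condition report to results/qc_report.csv.
"""

from pathlib import Path

import pandas as pd

from ktrquant.io import frame_to_csv
from ktrquant.qc import QcParams, flag_geometry, flag_outliers, qc_report

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "run_main"
RESULTS = ROOT / "results"


def main() -> None:
    cells = pd.read_csv(RUN_DIR / "cells.csv")
    params = QcParams()
    qced = flag_outliers(flag_geometry(cells, params), params)
    frame_to_csv(qced, RUN_DIR / "cells_qc.csv")
    RESULTS.mkdir(exist_ok=True)
    report = qc_report(qced)
    frame_to_csv(report, RESULTS / "qc_report.csv")
    print(report.to_string(index=False))
    print(f"\n{int(qced['qc_pass'].sum())}/{len(qced)} cells pass QC")


if __name__ == "__main__":
    main()
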