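"""Group statistics on QC-passing cells.

Per-condition summaries with per-field medians, Mann-Whitney comparisons
of activity and length between arms, and the per-cell joint
activity-by-length table with pooled/per-condition Spearman correlations.
Compact tables go to results/; the violin figure to scratch/figures/.
"""

from pathlib import Path

import pandas as pd

from ktrquant.io import frame_to_csv
from ktrquant.pipeline import _violin_figure
from ktrquant.stats import (MEASUREMENTS, activity_length_table,
                            compare_conditions, comparisons_to_frame,
                            summaries_to_frame, summarize)

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "run_main"
RESULTS = ROOT / "results"


def main() -> None:
    qced = pd.read_csv(RUN_DIR / "cells_qc.csv")
    passing = qced[qced["qc_pass"]]
    RESULTS.mkdir(exist_ok=True)

    summaries = summarize(passing)
    sframe = summaries_to_frame(summaries).round(4)
    frame_to_csv(sframe, RESULTS / "summaries.csv")
    print(sframe[["condition", "n_cells", "n_fields", "median_activity",
                  "median_length_px"]].to_string(index=False))

    results = [compare_conditions(passing, "DMSO", "SCH", m)
               for m in MEASUREMENTS]
    cframe = comparisons_to_frame(results)
    frame_to_csv(cframe, RESULTS / "comparisons.csv")
    print()
    print(cframe[["measurement", "U_statistic", "p_value", "n_a", "n_b",
                  "stars"]].to_string(index=False))

    joint, corr = activity_length_table(passing)
    # pooled correlation across both arms (inhibition shifts activity down
    # while lengthening processes, so pooled rho is negative)
    pooled = joint.assign(condition="pooled")
    _, pooled_corr = activity_length_table(pooled)
    corr = pd.concat([corr, pooled_corr], ignore_index=True).round(4)
    frame_to_csv(corr, RESULTS / "activity_length_correlations.csv")
    print()
    print(corr.to_string(index=False))

    fig_dir = ROOT / "scratch" / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    _violin_figure(passing, summaries, fig_dir / "violins.png")
    print(f"\nfigure: {fig_dir / 'violins.png'}")


if __name__ == "__main__":
    main()
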