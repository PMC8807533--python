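"""Validate the pipeline against the generator's ground truth.

Runs the segmentation fidelity benchmark, the activity-ratio recovery
experiment (true ratios uniform on [0.5, 3]) and the process-length
recovery experiment (true lengths uniform on [0, 120] px), and writes the
scores to results/recovery.json.
"""

import json
from pathlib import Path

from ktrquant.experiments import (activity_recovery_experiment,
                                  length_recovery_experiment,
                                  segmentation_benchmark)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 20260928


def main() -> None:
    out = {
        "segmentation": segmentation_benchmark(seed=SEED),
        "activity_recovery": activity_recovery_experiment(seed=SEED),
        "length_recovery": length_recovery_experiment(seed=SEED),
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "recovery.json").write_text(json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
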