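"""Generate the default synthetic cohort.

216 adaptive learners split over the four treatment conditions play three
blocks (baseline, treatment, baseline) of 15 rounds x 12 trials.  Writes
the long trial log, the per-participant parameter sidecar, and a run
manifest under results/.
"""

import json
import sys
from pathlib import Path

from trygiveup import CohortDesign, generate_cohort
from trygiveup.io import write_manifest, write_trial_log

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 12345) -> None:
    OUT.mkdir(exist_ok=True)
    design = CohortDesign(master_seed=seed)
    log, sidecar = generate_cohort(design)
    log_path = OUT / "cohort.csv"
    write_trial_log(log, log_path)
    sidecar_path = OUT / "cohort.participants.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    write_manifest(
        "analysis/02_simulate_cohort",
        {"design": "default", "seed": seed},
        seed,
        [log_path, sidecar_path],
        OUT / "cohort.manifest.json",
    )
    print(f"{len(log)} trials from {design.n_participants} participants -> {log_path}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 12345)
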