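"""Compute the dependent variables on the simulated cohort.

Reads results/cohort.csv, classifies choices where needed, strips
treatment-specific incentives, and writes per-participant-per-block rates
and payoffs (analysis window: trials 1-9) to results/metrics.csv.
"""

from pathlib import Path

from trygiveup import compute_rates
from trygiveup.io import read_trial_log

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    log = read_trial_log(OUT / "cohort.csv")
    rows = compute_rates(log, window=9)
    rows.to_csv(OUT / "metrics.csv", index=False, lineterminator="\n")
    by_block = rows.groupby("block")[["giveup_rate", "trylow_rate", "optimal_rate"]].mean()
    print("cohort means by block (window = trials 1-9):")
    print(by_block.round(3).to_string())
    print(f"\nwrote {OUT / 'metrics.csv'} ({len(rows)} participant-block rows)")


if __name__ == "__main__":
    main()
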