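"""Condition-level difference scores, ANOVA, and DV correlation.

Produces the condition x DV grid of treatment (block 2 - block 1) and
retention (block 3 - block 1) difference scores with 95% CIs, one-way
ANOVAs of the difference scores across conditions, and the per-condition
correlation between Give-Up and optimal choice rates.
"""

from pathlib import Path

import pandas as pd

from trygiveup import (
    anova_on_differences,
    difference_scores,
    dv_correlation,
    table2_report,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = pd.read_csv(OUT / "metrics.csv")
    diffs = difference_scores(rows)
    diffs.to_csv(OUT / "condition_differences.csv", index=False, lineterminator="\n")
    print("difference scores (rates in percentage points, payoffs in points/trial):")
    print(table2_report(diffs).to_string())

    print("\none-way ANOVAs of treatment-contrast difference scores:")
    for dv in ("giveup_rate", "trylow_rate", "optimal_rate", "mean_payoff_stripped"):
        res = anova_on_differences(rows, dv)
        print(
            f"  {dv:22s} F({res.df_between}, {res.df_within}) = {res.F:7.2f}, "
            f"p = {res.p:.4f}"
        )

    corr = dv_correlation(rows)
    print("\nr(giveup_rate, optimal_rate) by condition:")
    for cond, r in corr.by_condition.items():
        print(f"  {cond:28s} {r:+.3f}")
    print(f"  Fisher-z mean: {corr.mean_r:+.3f}")
    print(f"\nwrote {OUT / 'condition_differences.csv'}")


if __name__ == "__main__":
    main()
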