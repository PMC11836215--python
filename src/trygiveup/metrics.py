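"""Dependent variables, incentive stripping, difference scores, and simple
condition-level statistics on any conforming trial log.

The three dependent variables are computed per participant and block over
the analysis window (trials 1-9 by default, because the search-then-exploit
benchmark stops being the right yardstick late in a round): the Give-Up
choice rate, the Try-low exploitation rate (re-pressing familiar low Try
keys), and the optimal-benchmark consistency rate.  Payoffs are reported
both as displayed and with treatment-specific incentives stripped, i.e.
recomputed under the baseline scheme for the identical choice sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .policy import (
    CATEGORIES,
    GIVEUP_CAT,
    TRY_HIGH_EXPLOIT_CAT,
    TRY_LOW_EXPLOIT_CAT,
    classify_choice,
)
from .task import GIVEUP, TRY, TaskConfig, get_scheme

DV_RATE_COLUMNS = ("giveup_rate", "trylow_rate", "optimal_rate")
DV_COLUMNS = DV_RATE_COLUMNS + ("mean_payoff", "mean_payoff_stripped")

_ROUND_KEYS = ["participant_id", "condition", "block", "round"]


class SchemaError(ValueError):
    """Trial log does not conform to the expected schema."""


_REQUIRED = [
    "participant_id",
    "condition",
    "block",
    "round",
    "trial",
    "matrix",
    "key_id",
    "first_press",
    "raw_outcome",
    "scheme_delta",
    "cost_charged",
    "net_points",
]


def validate_log(log: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in log.columns]
    if missing:
        raise SchemaError(f"trial log is missing columns {missing}")
    bad = ~log["matrix"].isin([TRY, GIVEUP])
    if bad.any():
        raise SchemaError(
            f"bad matrix value at row {int(np.flatnonzero(bad.to_numpy())[0])}"
        )


def label_log(log: pd.DataFrame, config: TaskConfig | None = None) -> pd.DataFrame:
    """(Re)compute choice labels by replaying each round's revealed state.

    Works from the log alone: within each round, in trial order, a key's
    level is recovered from its raw outcome, and each choice is classified
    against the revealed state that preceded it.
    """
    config = config or TaskConfig()
    validate_log(log)
    log = log.sort_values(_ROUND_KEYS + ["trial"], kind="stable").reset_index(drop=True)
    labels = np.empty(len(log), dtype=object)
    optimal = np.zeros(len(log), dtype=int)
    matrices = log["matrix"].to_numpy()
    keys = log["key_id"].to_numpy()
    raws = log["raw_outcome"].to_numpy()
    bounds = log.groupby(_ROUND_KEYS, sort=False).indices.values()
    for idx in bounds:
        revealed: dict[str, dict[int, str]] = {TRY: {}, GIVEUP: {}}
        for i in idx:
            m, k = matrices[i], int(keys[i])
            lab = classify_choice(revealed, m, k)
            labels[i] = lab.category
            optimal[i] = int(lab.optimal_consistent)
            revealed[m][k] = config.spec(m).level_of(raws[i])
    out = log.copy()
    out["label"] = labels
    out["optimal"] = optimal
    return out


def strip_incentives(log: pd.DataFrame, config: TaskConfig | None = None) -> pd.DataFrame:
    """Add ``net_points_stripped``: each trial's payoff under baseline rules.

    The baseline scheme has no outcome deltas and charges its exploration
    cost on every first press, so stripping is exact: raw outcome minus
    baseline cost where the press was a first press.  Equal to a baseline
    replay of the identical choice sequence.
    """
    config = config or TaskConfig()
    validate_log(log)
    baseline = get_scheme("baseline")
    cost = log["matrix"].map({m: baseline.cost(m) for m in (TRY, GIVEUP)})
    out = log.copy()
    out["net_points_stripped"] = log["raw_outcome"] - cost * log["first_press"].astype(
        float
    )
    return out


def compute_rates(
    log: pd.DataFrame,
    window: int = 9,
    config: TaskConfig | None = None,
) -> pd.DataFrame:
    """Per participant x block: DV rates and mean payoffs over the window.

    Rates are category counts divided by the number of windowed trials
    (choices, not opportunities).  Labels are recomputed by replay when the
    log does not carry them.
    """
    config = config or TaskConfig()
    validate_log(log)
    if "label" not in log.columns or log["label"].isna().any():
        log = label_log(log, config)
    if "net_points_stripped" not in log.columns:
        log = strip_incentives(log, config)
    win = log[log["trial"] <= window]
    grouped = win.groupby(["participant_id", "condition", "block"], sort=True)
    rows = grouped.apply(
        lambda g: pd.Series(
            {
                "giveup_rate": (g["label"] == GIVEUP_CAT).mean(),
                "trylow_rate": (g["label"] == TRY_LOW_EXPLOIT_CAT).mean(),
                "tryhigh_rate": (g["label"] == TRY_HIGH_EXPLOIT_CAT).mean(),
                "optimal_rate": g["optimal"].mean(),
                "mean_payoff": g["net_points"].mean(),
                "mean_payoff_stripped": g["net_points_stripped"].mean(),
                "n_trials": len(g),
            }
        ),
        include_groups=False,
    ).reset_index()
    rows["n_trials"] = rows["n_trials"].astype(int)
    return rows


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def anova_oneway(groups: Sequence[np.ndarray | Sequence[float]]) -> AnovaResult:
    """Plain one-way between-subjects ANOVA by the standard decomposition.

    A zero within-group mean square (all groups internally constant, but
    group means differ) is degenerate: F is reported as infinite with a
    warning rather than raising.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g in arrays:
        if len(g) < 2:
            raise ValueError("inference refused: every group needs >= 2 observations")
    n_total = sum(len(g) for g in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        if ms_b == 0.0:
            return AnovaResult(np.nan, df_b, df_w, np.nan)
        warnings.warn(
            "zero within-group variance: F is infinite", RuntimeWarning, stacklevel=2
        )
        return AnovaResult(float("inf"), df_b, df_w, 0.0)
    F = ms_b / ms_w
    return AnovaResult(float(F), df_b, df_w, float(stats.f.sf(F, df_b, df_w)))


def difference_scores(
    rows: pd.DataFrame,
    *,
    baseline_block: int = 1,
    contrasts: Mapping[str, int] | None = None,
    rate_scale: float = 100.0,
    ci_method: str = "normal",
    n_boot: int = 2000,
    rng: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-condition mean difference scores with 95% CIs.

    For each participant and DV, the difference between a contrast block
    and the baseline block is taken (``treatment`` = block 2 - block 1,
    ``retention`` = block 3 - block 1 by default); rates are scaled to
    percentage points.  CIs are normal-approximation (mean +/- 1.96 SE)
    across participants, or percentile bootstrap when requested.
    """
    if contrasts is None:
        contrasts = {"treatment": 2, "retention": 3}
    if ci_method not in ("normal", "bootstrap"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    wide = rows.pivot_table(
        index=["participant_id", "condition"],
        columns="block",
        values=list(DV_COLUMNS),
        sort=True,
    )
    out = []
    for contrast, blk in contrasts.items():
        for dv in DV_COLUMNS:
            scale = rate_scale if dv in DV_RATE_COLUMNS else 1.0
            diff = (wide[(dv, blk)] - wide[(dv, baseline_block)]) * scale
            for cond, vals in diff.groupby(level="condition", sort=True):
                v = vals.dropna().to_numpy()
                n = len(v)
                mean = float(v.mean()) if n else np.nan
                if n < 2:
                    warnings.warn(
                        f"condition {cond!r} has {n} participant(s); CI not computed",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    lo = hi = np.nan
                elif ci_method == "normal":
                    se = v.std(ddof=1) / np.sqrt(n)
                    lo, hi = mean - 1.96 * se, mean + 1.96 * se
                else:
                    idx = rng.integers(0, n, size=(n_boot, n))
                    boots = v[idx].mean(axis=1)
                    lo, hi = np.percentile(boots, [2.5, 97.5])
                out.append(
                    {
                        "condition": cond,
                        "dv": dv,
                        "contrast": contrast,
                        "mean": mean,
                        "ci_low": float(lo),
                        "ci_high": float(hi),
                        "n": n,
                    }
                )
    return pd.DataFrame(out)


@dataclass(frozen=True)
class CorrelationResult:
    by_condition: Mapping[str, float]
    fisher_z_mean: float
    mean_r: float


_R_CLAMP = 1.0 - 1e-12


def dv_correlation(
    rows: pd.DataFrame, x: str = "giveup_rate", y: str = "optimal_rate"
) -> CorrelationResult:
    """Per-condition Pearson r between two DVs, with the Fisher-z average.

    Computed across participant-block rows within each condition; |r| is
    clamped just below 1 so degenerate perfect correlations stay finite
    under the z transform.
    """
    by_cond: dict[str, float] = {}
    for cond, g in rows.groupby("condition", sort=True):
        r = float(np.corrcoef(g[x], g[y])[0, 1])
        by_cond[cond] = r
    zs = [np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP)) for r in by_cond.values()]
    zbar = float(np.mean(zs))
    return CorrelationResult(by_cond, zbar, float(np.tanh(zbar)))


def anova_on_differences(
    rows: pd.DataFrame, dv: str, contrast_block: int = 2, baseline_block: int = 1
) -> AnovaResult:
    """One-way ANOVA of per-participant difference scores across conditions."""
    wide = rows.pivot_table(
        index=["participant_id", "condition"], columns="block", values=dv, sort=True
    )
    diff = (wide[contrast_block] - wide[baseline_block]).dropna()
    groups = [
        g.to_numpy() for _, g in diff.groupby(level="condition", sort=True)
    ]
    return anova_oneway(groups)


def table2_report(diffs: pd.DataFrame) -> pd.DataFrame:
    """Pivot the difference table into a condition x DV x contrast grid."""
    out = diffs.copy()
    out["cell"] = out.apply(
        lambda r: f"{r['mean']:.1f} [{r['ci_low']:.1f}, {r['ci_high']:.1f}]", axis=1
    )
    return out.pivot_table(
        index=["contrast", "dv"],
        columns="condition",
        values="cell",
        aggfunc="first",
        sort=True,
    )


def category_shares(log: pd.DataFrame, window: int = 9) -> pd.DataFrame:
    """Shares of the four choice categories per participant-block window."""
    validate_log(log)
    if "label" not in log.columns:
        log = label_log(log)
    win = log[log["trial"] <= window]
    shares = (
        win.groupby(["participant_id", "block"], sort=True)["label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    for cat in CATEGORIES:
        if cat not in shares.columns:
            shares[cat] = 0.0
    return shares[list(CATEGORIES)]
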