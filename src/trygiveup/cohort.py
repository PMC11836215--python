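"""Synthetic-cohort generator: full three-block, four-condition experiments.

Each simulated participant is an independently drawn agent with persistent
parameters who plays a pretreatment baseline block, a treatment block under
their condition's incentive scheme, and a posttreatment baseline block.
The shipped defaults emulate the study design this package analyses:
four between-subject conditions with 53/55/54/54 participants, 3 blocks x
15 rounds x 12 trials, learning across rounds, condition-dependent shifts
during treatment, and partial retention afterwards.  Participant
heterogeneity comes from truncated-normal draws of the learner parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .agents import (
    AGENT_KINDS,
    AgentSpec,
    make_agent,
    play_block,
)
from .task import ConfigError, TaskConfig, TreatmentScheme, get_scheme

DEFAULT_CONDITIONS = (
    "minus_giveup",
    "minus_giveup_minus_trylow",
    "plus_try",
    "plus_try_explore",
)
DEFAULT_N_PER_CONDITION = (53, 55, 54, 54)


@dataclass(frozen=True)
class ParamDist:
    """Truncated normal distribution for a heterogeneous agent parameter."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("sd must be >= 0")
        if self.lower > self.upper:
            raise ConfigError("lower bound exceeds upper bound")

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return float(np.clip(self.mean, self.lower, self.upper))
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return float(
            stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, random_state=rng)
        )


DEFAULT_LEARNER_DISTS: Mapping[str, ParamDist] = {
    "learning_rate": ParamDist(0.25, 0.10, 0.02, 0.80),
    "temperature": ParamDist(5.0, 2.0, 1.0, 15.0),
    "retention_decay": ParamDist(0.5, 0.2, 0.05, 0.95),
}
DEFAULT_INITIAL_PROPENSITIES = (14.0, 10.0, 8.0)


@dataclass(frozen=True)
class CohortDesign:
    """Design of one synthetic experiment."""

    task: TaskConfig = TaskConfig()
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_per_condition: tuple[int, ...] = DEFAULT_N_PER_CONDITION
    agent_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"adaptive_learner": 1.0}
    )
    learner_dists: Mapping[str, ParamDist] = field(
        default_factory=lambda: dict(DEFAULT_LEARNER_DISTS)
    )
    initial_propensities: tuple[float, ...] = DEFAULT_INITIAL_PROPENSITIES
    threshold_m: int = 12  # m for any threshold_try agents in the mixture
    master_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) != len(self.n_per_condition):
            raise ConfigError("conditions and n_per_condition lengths differ")
        for n in self.n_per_condition:
            if n < 1:
                raise ConfigError("n per condition must be >= 1")
        for name in self.conditions:
            get_scheme(name)
        weights = dict(self.agent_mixture)
        if not weights:
            raise ConfigError("agent_mixture must not be empty")
        for kind, w in weights.items():
            if kind not in AGENT_KINDS:
                raise ConfigError(f"unknown agent kind in mixture: {kind!r}")
            if w < 0:
                raise ConfigError("mixture weights must be >= 0")
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise ConfigError("mixture weights must sum to 1")

    @property
    def n_participants(self) -> int:
        return int(sum(self.n_per_condition))


def _draw_agent_spec(design: CohortDesign, rng: np.random.Generator) -> AgentSpec:
    kinds = sorted(design.agent_mixture)
    weights = np.array([design.agent_mixture[k] for k in kinds])
    kind = kinds[rng.choice(len(kinds), p=weights / weights.sum())]
    if kind == "adaptive_learner":
        params = {name: dist.sample(rng) for name, dist in design.learner_dists.items()}
        params["initial_propensities"] = tuple(design.initial_propensities)
        return AgentSpec(kind, params)
    if kind == "threshold_try":
        return AgentSpec(kind, {"m": design.threshold_m})
    return AgentSpec(kind)


def generate_cohort(
    design: CohortDesign,
    *,
    master_seed: int | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate the full cohort; returns the long trial log and a sidecar.

    One row per trial: participants x blocks x rounds x trials.  The
    sidecar lists each participant's realised agent kind and parameters.
    Deterministic given the master seed (``master_seed`` overrides the
    design's own).
    """
    seed = design.master_seed if master_seed is None else master_seed
    root = np.random.SeedSequence(seed)
    children = root.spawn(design.n_participants)

    all_records = []
    sidecar: list[dict] = []
    pid = 0
    for cond, n in zip(design.conditions, design.n_per_condition):
        config = design.task.with_treatment(cond)
        for _ in range(n):
            rng = np.random.default_rng(children[pid])
            participant_id = f"P{pid + 1:03d}"
            spec = _draw_agent_spec(design, rng)
            # dp_optimal in a mixture plays each block under that block's
            # scheme-solved policy; other kinds ignore the scheme argument.
            sidecar.append(
                {
                    "participant_id": participant_id,
                    "condition": cond,
                    "kind": spec.kind,
                    "params": {
                        k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in dict(spec.params).items()
                    },
                }
            )
            agent = None
            for block_no, scheme_name in enumerate(config.block_schemes, start=1):
                scheme: TreatmentScheme = get_scheme(scheme_name)
                if agent is None or spec.kind == "dp_optimal":
                    agent = make_agent(spec, config, scheme)
                all_records.extend(
                    play_block(
                        agent,
                        config,
                        scheme,
                        config.rounds_per_block,
                        rng,
                        participant_id=participant_id,
                        condition=cond,
                        block=block_no,
                    )
                )
            pid += 1

    frame = pd.DataFrame([vars(r) for r in all_records])
    frame["first_press"] = frame["first_press"].astype(int)
    frame["optimal"] = frame["optimal"].astype(int)
    return frame, sidecar


def bonus_round_payoffs(
    log: pd.DataFrame, rng: int | np.random.Generator
) -> pd.DataFrame:
    """Optional bonus-sampling utility: one random round per block.

    For each participant, draws one round per block and averages the three
    round totals, mirroring a pay-one-round-per-block incentive rule.
    Purely a summary; generation never depends on it.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    totals = (
        log.groupby(["participant_id", "block", "round"], sort=True)["net_points"]
        .sum()
        .reset_index()
    )
    rows = []
    for pid, g in totals.groupby("participant_id", sort=True):
        picks = []
        for _, gb in g.groupby("block", sort=True):
            picks.append(gb["net_points"].iloc[rng.integers(len(gb))])
        rows.append({"participant_id": pid, "bonus_points": float(np.mean(picks))})
    return pd.DataFrame(rows)
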