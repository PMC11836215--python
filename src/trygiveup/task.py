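"""Incentive structure and single-round simulation of the Try-or-Give-Up task.

The task presents two 12-key matrices.  Each key holds a latent outcome fixed
for the duration of a round: *Try* keys are worth +1 with probability .9 and
+14 with probability .1; *Give-Up* keys are worth +1 or +2 with equal
probability.  Pressing a key for the first time in a round reveals its
outcome and charges an exploration cost (2 points at baseline); re-pressing
a revealed key harvests its value at no cost.

Treatment schemes modify this structure additively (per-level outcome
deltas) or by waiving exploration costs, which is exactly how the four
shipped interventions are encoded.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping

import numpy as np

TRY = "try"
GIVEUP = "giveup"
MATRICES = (TRY, GIVEUP)

LOW = "low"
HIGH = "high"
LEVELS = (LOW, HIGH)


class ConfigError(ValueError):
    """Invalid task, scheme, agent, or design configuration."""


class StateError(RuntimeError):
    """Operation applied to a round state that cannot accept it."""


@dataclass(frozen=True)
class MatrixSpec:
    """Outcome distribution of one key matrix.

    Each of ``n_keys`` keys is independently assigned ``high_value`` with
    probability ``p_high``, else ``low_value``, at the start of a round.
    """

    low_value: float
    high_value: float
    p_high: float
    n_keys: int = 12

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_high <= 1.0:
            raise ConfigError(f"p_high must be in [0, 1], got {self.p_high}")
        if self.n_keys < 1:
            raise ConfigError(f"n_keys must be >= 1, got {self.n_keys}")
        if self.high_value < self.low_value:
            raise ConfigError(
                f"high_value ({self.high_value}) < low_value ({self.low_value})"
            )

    def value(self, level: str) -> float:
        if level == HIGH:
            return self.high_value
        if level == LOW:
            return self.low_value
        raise ValueError(f"unknown level {level!r}")

    def level_of(self, raw_outcome: float) -> str:
        """Classify a raw outcome back into its level.

        When ``low_value == high_value`` the levels are indistinguishable
        from outcomes alone; the value is reported as high.
        """
        return HIGH if raw_outcome == self.high_value else LOW


@dataclass(frozen=True)
class TreatmentScheme:
    """Additive payoff transformation applied during one block.

    ``outcome_delta`` maps ``(matrix, level)`` to the points added to every
    press of a key of that kind (exploration and exploitation alike).
    ``exploration_cost`` maps a matrix to the nonnegative cost charged on
    the first press of each of its keys.
    """

    name: str
    outcome_delta: Mapping[tuple[str, str], float] = field(default_factory=dict)
    exploration_cost: Mapping[str, float] = field(
        default_factory=lambda: {TRY: 2.0, GIVEUP: 2.0}
    )

    def __post_init__(self) -> None:
        for (matrix, level), d in self.outcome_delta.items():
            if matrix not in MATRICES or level not in LEVELS:
                raise ConfigError(f"bad outcome_delta key {(matrix, level)!r}")
            float(d)
        for matrix, c in self.exploration_cost.items():
            if matrix not in MATRICES:
                raise ConfigError(f"bad exploration_cost key {matrix!r}")
            if c < 0:
                raise ConfigError(f"exploration cost must be >= 0, got {c}")
        object.__setattr__(
            self, "outcome_delta", MappingProxyType(dict(self.outcome_delta))
        )
        object.__setattr__(
            self, "exploration_cost", MappingProxyType(dict(self.exploration_cost))
        )

    def delta(self, matrix: str, level: str) -> float:
        return float(self.outcome_delta.get((matrix, level), 0.0))

    def cost(self, matrix: str) -> float:
        return float(self.exploration_cost.get(matrix, 0.0))


def build_schemes(
    *, penalty: float = 2.0, reward: float = 2.0, base_cost: float = 2.0
) -> dict[str, TreatmentScheme]:
    """The five named schemes: baseline plus the four interventions.

    - ``baseline``: no deltas, exploration cost ``base_cost`` everywhere.
    - ``minus_giveup``: every Give-Up outcome is penalised.
    - ``minus_giveup_minus_trylow``: Give-Up outcomes and low Try outcomes
      are penalised (low Try presses are penalised even on a first press
      that merely reveals a low key).
    - ``plus_try``: every Try outcome is rewarded.
    - ``plus_try_explore``: Try exploration costs are waived (the reward
      exactly offsets the first-press cost); Give-Up costs are unchanged.
    """
    cost = {TRY: base_cost, GIVEUP: base_cost}
    return {
        "baseline": TreatmentScheme("baseline", {}, cost),
        "minus_giveup": TreatmentScheme(
            "minus_giveup",
            {(GIVEUP, LOW): -penalty, (GIVEUP, HIGH): -penalty},
            cost,
        ),
        "minus_giveup_minus_trylow": TreatmentScheme(
            "minus_giveup_minus_trylow",
            {
                (GIVEUP, LOW): -penalty,
                (GIVEUP, HIGH): -penalty,
                (TRY, LOW): -penalty,
            },
            cost,
        ),
        "plus_try": TreatmentScheme(
            "plus_try",
            {(TRY, LOW): reward, (TRY, HIGH): reward},
            cost,
        ),
        "plus_try_explore": TreatmentScheme(
            "plus_try_explore",
            {},
            {TRY: 0.0, GIVEUP: base_cost},
        ),
    }


SCHEMES: dict[str, TreatmentScheme] = build_schemes()
SCHEME_NAMES = tuple(SCHEMES)
TREATMENT_NAMES = tuple(n for n in SCHEME_NAMES if n != "baseline")


def get_scheme(name: str, schemes: Mapping[str, TreatmentScheme] | None = None) -> TreatmentScheme:
    table = SCHEMES if schemes is None else schemes
    try:
        return table[name]
    except KeyError:
        raise ConfigError(
            f"unknown scheme {name!r}; known schemes: {sorted(table)}"
        ) from None


@dataclass(frozen=True)
class TaskConfig:
    """Full task parameterisation; the defaults are the shipped incentive design."""

    try_spec: MatrixSpec = MatrixSpec(1.0, 14.0, 0.1, 12)
    giveup_spec: MatrixSpec = MatrixSpec(1.0, 2.0, 0.5, 12)
    trials_per_round: int = 12
    rounds_per_block: int = 15
    block_schemes: tuple[str, ...] = ("baseline", "baseline", "baseline")
    analysis_window: int = 9

    def __post_init__(self) -> None:
        if self.trials_per_round < 1:
            raise ConfigError("trials_per_round must be >= 1")
        if self.rounds_per_block < 1:
            raise ConfigError("rounds_per_block must be >= 1")
        if not 1 <= self.analysis_window <= self.trials_per_round:
            raise ConfigError(
                "analysis_window must be in [1, trials_per_round], got "
                f"{self.analysis_window}"
            )

    def spec(self, matrix: str) -> MatrixSpec:
        if matrix == TRY:
            return self.try_spec
        if matrix == GIVEUP:
            return self.giveup_spec
        raise ValueError(f"unknown matrix {matrix!r}")

    def with_treatment(self, treatment: str) -> "TaskConfig":
        """Three-block design with the given scheme in the middle block."""
        get_scheme(treatment)
        return replace(self, block_schemes=("baseline", treatment, "baseline"))


@dataclass
class RoundState:
    """Mutable state of one round in progress.

    ``latent_levels`` is assigned at round start and never changes;
    ``revealed`` holds the level of every key pressed so far.  Once
    revealed, a key's outcome stays fixed until the round ends.
    """

    latent_levels: dict[str, tuple[str, ...]]
    revealed: dict[str, dict[int, str]]
    trial_index: int = 1
    cumulative_points: float = 0.0

    def revealed_levels(self, matrix: str) -> dict[int, str]:
        return dict(self.revealed[matrix])

    def copy(self) -> "RoundState":
        return RoundState(
            latent_levels=self.latent_levels,
            revealed=copy.deepcopy(self.revealed),
            trial_index=self.trial_index,
            cumulative_points=self.cumulative_points,
        )


@dataclass
class TrialRecord:
    """One row of the universal trial log.

    ``net_points = raw_outcome + scheme_delta - cost_charged`` holds on
    every record; the decomposition lets treatment-specific incentives be
    stripped exactly afterwards.
    """

    participant_id: str
    condition: str
    block: int
    round: int
    trial: int
    matrix: str
    key_id: int
    first_press: bool
    raw_outcome: float
    scheme_delta: float
    cost_charged: float
    net_points: float
    label: str = ""
    optimal: bool = False


def _as_rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_round(
    config: TaskConfig, seed: int | np.random.Generator | np.random.SeedSequence
) -> RoundState:
    """Draw latent key outcomes for a fresh round.

    Each key is independently high with its matrix's ``p_high``.  Nothing
    is revealed; the trial counter starts at 1.  Bit-reproducible for a
    fixed seed.
    """
    rng = _as_rng(seed)
    latent: dict[str, tuple[str, ...]] = {}
    for matrix in MATRICES:
        spec = config.spec(matrix)
        draws = rng.random(spec.n_keys) < spec.p_high
        latent[matrix] = tuple(HIGH if d else LOW for d in draws)
    return RoundState(latent_levels=latent, revealed={TRY: {}, GIVEUP: {}})


def apply_scheme(
    scheme: TreatmentScheme, matrix: str, level: str, first_press: bool
) -> tuple[float, float]:
    """Return ``(scheme_delta, cost_charged)`` for one press.

    Deltas apply on every press of a key of the given level; the
    exploration cost is charged only on a first press, at the scheme's
    per-matrix rate.
    """
    if matrix not in MATRICES:
        raise ValueError(f"unknown matrix {matrix!r}")
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    delta = scheme.delta(matrix, level)
    cost = scheme.cost(matrix) if first_press else 0.0
    return delta, cost


def step(
    state: RoundState,
    config: TaskConfig,
    scheme: TreatmentScheme,
    matrix: str,
    key_id: int,
    *,
    participant_id: str = "",
    condition: str = "",
    block: int = 1,
    round_no: int = 1,
) -> tuple[TrialRecord, RoundState]:
    """Press one key: reveal it if fresh, emit the trial record, advance.

    Mutates ``state`` in place and returns it alongside the record.
    """
    if state.trial_index > config.trials_per_round:
        raise StateError(
            f"round is over (trial {state.trial_index} > {config.trials_per_round})"
        )
    spec = config.spec(matrix)
    if not 0 <= key_id < spec.n_keys:
        raise ValueError(f"key_id {key_id} out of range for {matrix} matrix")

    first_press = key_id not in state.revealed[matrix]
    level = state.latent_levels[matrix][key_id]
    raw = spec.value(level)
    delta, cost = apply_scheme(scheme, matrix, level, first_press)
    net = raw + delta - cost

    record = TrialRecord(
        participant_id=participant_id,
        condition=condition,
        block=block,
        round=round_no,
        trial=state.trial_index,
        matrix=matrix,
        key_id=key_id,
        first_press=first_press,
        raw_outcome=raw,
        scheme_delta=delta,
        cost_charged=cost,
        net_points=net,
    )
    state.revealed[matrix][key_id] = level
    state.trial_index += 1
    state.cumulative_points += net
    return record, state
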