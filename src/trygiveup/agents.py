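"""Round-playing agents: fixed heuristics, the threshold family, the
DP-optimal policy follower, and a meta-strategy reinforcement learner.

Agents observe only revealed outcomes — ``RoundView`` exposes the revealed
key levels and counters, never the latent values — so no agent can peek at
unexplored keys.  The two fixed heuristics operationalise the task's two
local maxima: settling for Give-Up rewards, and settling on a familiar
low-value Try key to dodge exploration costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .policy import (
    BeliefState,
    EXPLOIT_GIVEUP_HIGH,
    EXPLOIT_GIVEUP_LOW,
    EXPLOIT_TRY_HIGH,
    EXPLOIT_TRY_LOW,
    EXPLORE_GIVEUP,
    EXPLORE_TRY,
    HIGH,
    LOW,
    NONE,
    PolicyTable,
    classify_choice,
    solve_dp,
)
from .task import (
    GIVEUP,
    TRY,
    ConfigError,
    RoundState,
    TaskConfig,
    TreatmentScheme,
    TrialRecord,
    get_scheme,
    sample_round,
    step,
)

AGENT_KINDS = (
    "giveup_searcher",
    "trylow_settler",
    "threshold_try",
    "dp_optimal",
    "adaptive_learner",
)

META_STRATEGIES = ("giveup_search", "trylow_settle", "try_search")

_ALLOWED_PARAMS = {
    "giveup_searcher": set(),
    "trylow_settler": set(),
    "threshold_try": {"m"},
    "dp_optimal": set(),
    "adaptive_learner": {
        "learning_rate",
        "temperature",
        "retention_decay",
        "initial_propensities",
    },
}


@dataclass(frozen=True)
class AgentSpec:
    """Declarative agent description; parameters are validated per kind."""

    kind: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ConfigError(f"unknown agent kind {self.kind!r}; known: {AGENT_KINDS}")
        unknown = set(self.params) - _ALLOWED_PARAMS[self.kind]
        if unknown:
            raise ConfigError(
                f"agent kind {self.kind!r} does not accept parameters {sorted(unknown)}"
            )
        if self.kind == "threshold_try" and "m" not in self.params:
            raise ConfigError("threshold_try requires parameter 'm'")


class RoundView:
    """Read-only view of one round as the agent is allowed to see it."""

    __slots__ = ("revealed", "trial_index", "trials_per_round", "n_keys")

    def __init__(self, state: RoundState, config: TaskConfig) -> None:
        self.revealed = {m: dict(state.revealed[m]) for m in (TRY, GIVEUP)}
        self.trial_index = state.trial_index
        self.trials_per_round = config.trials_per_round
        self.n_keys = {m: config.spec(m).n_keys for m in (TRY, GIVEUP)}

    @property
    def trials_remaining(self) -> int:
        return self.trials_per_round - self.trial_index + 1

    def fresh_key(self, matrix: str) -> int | None:
        """Lowest-index unexplored key, or None."""
        seen = self.revealed[matrix]
        for k in range(self.n_keys[matrix]):
            if k not in seen:
                return k
        return None

    def keys_at(self, matrix: str, level: str) -> list[int]:
        return sorted(k for k, lvl in self.revealed[matrix].items() if lvl == level)

    def best_known(self, matrix: str) -> int | None:
        """Key index of the best revealed key (high preferred), or None."""
        highs = self.keys_at(matrix, HIGH)
        if highs:
            return highs[0]
        lows = self.keys_at(matrix, LOW)
        return lows[0] if lows else None


class Agent:
    """Base agent; subclasses implement :meth:`choose`.

    The lifecycle hooks are no-ops for fixed strategies and drive learning
    for the adaptive learner.
    """

    def choose(self, view: RoundView, rng: np.random.Generator) -> tuple[str, int]:
        raise NotImplementedError

    def begin_block(self, scheme_name: str) -> None:  # noqa: B027
        pass

    def begin_round(self, rng: np.random.Generator) -> None:  # noqa: B027
        pass

    def end_round(self, round_payoff: float) -> None:  # noqa: B027
        pass


class GiveUpSearcher(Agent):
    """Explore fresh Give-Up keys until a high one is found, then exploit it."""

    def choose(self, view: RoundView, rng: np.random.Generator) -> tuple[str, int]:
        highs = view.keys_at(GIVEUP, HIGH)
        if highs:
            return GIVEUP, highs[0]
        fresh = view.fresh_key(GIVEUP)
        if fresh is not None:
            return GIVEUP, fresh
        return GIVEUP, view.best_known(GIVEUP)


class TryLowSettler(Agent):
    """Explore one Try key, then exploit it for the rest of the round."""

    def choose(self, view: RoundView, rng: np.random.Generator) -> tuple[str, int]:
        revealed = view.revealed[TRY]
        if not revealed:
            return TRY, view.fresh_key(TRY)
        return TRY, min(revealed)


class ThresholdTry(Agent):
    """The S_m strategy: Try search with a switch after m failures."""

    def __init__(self, m: int) -> None:
        if m < 0:
            raise ConfigError(f"threshold m must be >= 0, got {m}")
        self.m = m

    def choose(self, view: RoundView, rng: np.random.Generator) -> tuple[str, int]:
        highs = view.keys_at(TRY, HIGH)
        if highs:
            return TRY, highs[0]
        failures = len(view.keys_at(TRY, LOW))
        if failures < self.m:
            fresh = view.fresh_key(TRY)
            if fresh is not None:
                return TRY, fresh
        # Give-Up phase
        gu_highs = view.keys_at(GIVEUP, HIGH)
        if gu_highs:
            return GIVEUP, gu_highs[0]
        fresh = view.fresh_key(GIVEUP)
        if fresh is not None:
            return GIVEUP, fresh
        best = view.best_known(GIVEUP)
        if best is not None:
            return GIVEUP, best
        # Degenerate: no Give-Up key ever available to exploit; fall back to
        # the best known Try key.
        return TRY, view.best_known(TRY)


class DPOptimal(Agent):
    """Follows a solved :class:`PolicyTable` exactly."""

    def __init__(self, policy: PolicyTable) -> None:
        self.policy = policy

    def _belief(self, view: RoundView) -> BeliefState:
        def best(matrix: str) -> str:
            if view.keys_at(matrix, HIGH):
                return HIGH
            if view.keys_at(matrix, LOW):
                return LOW
            return NONE

        return BeliefState(
            view.trials_remaining,
            best(TRY),
            best(GIVEUP),
            view.n_keys[TRY] - len(view.revealed[TRY]),
            view.n_keys[GIVEUP] - len(view.revealed[GIVEUP]),
        )

    def choose(self, view: RoundView, rng: np.random.Generator) -> tuple[str, int]:
        action = self.policy.action(self._belief(view))
        if action == EXPLORE_TRY:
            return TRY, view.fresh_key(TRY)
        if action == EXPLORE_GIVEUP:
            return GIVEUP, view.fresh_key(GIVEUP)
        if action == EXPLOIT_TRY_HIGH:
            return TRY, view.keys_at(TRY, HIGH)[0]
        if action == EXPLOIT_TRY_LOW:
            return TRY, view.keys_at(TRY, LOW)[0]
        if action == EXPLOIT_GIVEUP_HIGH:
            return GIVEUP, view.keys_at(GIVEUP, HIGH)[0]
        if action == EXPLOIT_GIVEUP_LOW:
            return GIVEUP, view.keys_at(GIVEUP, LOW)[0]
        raise RuntimeError(f"no action available in state {self._belief(view)}")


class AdaptiveLearner(Agent):
    """Round-level meta-strategy learner.

    Each round the learner picks one meta-strategy — Give-Up search,
    Try-low settling, or Try search — by softmax over propensities
    (temperature ``tau``), plays the round with it, and moves the chosen
    propensity toward the realised round payoff by step ``alpha``.  When
    the incentive scheme changes between blocks, propensities decay toward
    their initial values by fraction ``rho`` (1 = full reset, 0 = full
    persistence), which is what produces partial retention of treatment
    effects after incentives are removed.
    """

    def __init__(
        self,
        config: TaskConfig,
        learning_rate: float = 0.25,
        temperature: float = 5.0,
        retention_decay: float = 0.5,
        initial_propensities: tuple[float, float, float] = (14.0, 10.0, 8.0),
    ) -> None:
        # zero is allowed as the degenerate no-learning case
        if not 0.0 <= learning_rate <= 1.0:
            raise ConfigError(f"learning_rate must be in [0, 1], got {learning_rate}")
        if temperature <= 0.0:
            raise ConfigError(f"temperature must be > 0, got {temperature}")
        if not 0.0 <= retention_decay <= 1.0:
            raise ConfigError(
                f"retention_decay must be in [0, 1], got {retention_decay}"
            )
        if len(initial_propensities) != len(META_STRATEGIES):
            raise ConfigError(
                f"need {len(META_STRATEGIES)} initial propensities "
                f"(one per meta-strategy {META_STRATEGIES})"
            )
        self.alpha = float(learning_rate)
        self.tau = float(temperature)
        self.rho = float(retention_decay)
        self.q0 = np.asarray(initial_propensities, dtype=float)
        self.q = self.q0.copy()
        self._inner = {
            "giveup_search": GiveUpSearcher(),
            "trylow_settle": TryLowSettler(),
            "try_search": ThresholdTry(config.trials_per_round),
        }
        self._current: str | None = None
        self._last_scheme: str | None = None

    @property
    def propensities(self) -> np.ndarray:
        return self.q.copy()

    def meta_probabilities(self) -> np.ndarray:
        if not np.all(np.isfinite(self.q)):
            raise FloatingPointError(f"non-finite propensities: {self.q}")
        z = (self.q - self.q.max()) / self.tau
        w = np.exp(z)
        return w / w.sum()

    def begin_block(self, scheme_name: str) -> None:
        if self._last_scheme is not None and scheme_name != self._last_scheme:
            self.q = self.rho * self.q0 + (1.0 - self.rho) * self.q
        self._last_scheme = scheme_name

    def begin_round(self, rng: np.random.Generator) -> None:
        p = self.meta_probabilities()
        self._current = META_STRATEGIES[rng.choice(len(META_STRATEGIES), p=p)]

    def choose(self, view: RoundView, rng: np.random.Generator) -> tuple[str, int]:
        if self._current is None:
            raise RuntimeError("begin_round must be called before choose")
        return self._inner[self._current].choose(view, rng)

    def end_round(self, round_payoff: float) -> None:
        if self._current is None:
            return
        i = META_STRATEGIES.index(self._current)
        self.q[i] += self.alpha * (round_payoff - self.q[i])
        if not np.all(np.isfinite(self.q)):
            raise FloatingPointError(f"non-finite propensities after update: {self.q}")
        self._current = None


def update_learner(agent: AdaptiveLearner, round_payoff: float) -> AdaptiveLearner:
    """Functional wrapper for the learner's propensity update."""
    agent.end_round(round_payoff)
    return agent


def make_agent(
    spec: AgentSpec,
    config: TaskConfig,
    scheme: str | TreatmentScheme = "baseline",
) -> Agent:
    """Instantiate an agent; ``dp_optimal`` solves its policy for the scheme."""
    if spec.kind == "giveup_searcher":
        return GiveUpSearcher()
    if spec.kind == "trylow_settler":
        return TryLowSettler()
    if spec.kind == "threshold_try":
        return ThresholdTry(int(spec.params["m"]))
    if spec.kind == "dp_optimal":
        scheme_obj = get_scheme(scheme) if isinstance(scheme, str) else scheme
        return DPOptimal(solve_dp(config, scheme_obj))
    if spec.kind == "adaptive_learner":
        return AdaptiveLearner(config, **dict(spec.params))
    raise ConfigError(f"unknown agent kind {spec.kind!r}")


def play_round(
    agent: Agent,
    config: TaskConfig,
    scheme: TreatmentScheme,
    rng: int | np.random.Generator,
    *,
    participant_id: str = "",
    condition: str = "",
    block: int = 1,
    round_no: int = 1,
) -> list[TrialRecord]:
    """Play one full round; returns exactly ``trials_per_round`` records.

    Choices are classified against the optimal benchmark as they are made,
    using only the revealed state visible before each trial.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    state = sample_round(config, rng)
    agent.begin_round(rng)
    records: list[TrialRecord] = []
    for _ in range(config.trials_per_round):
        view = RoundView(state, config)
        matrix, key_id = agent.choose(view, rng)
        label = classify_choice(view.revealed, matrix, key_id)
        record, state = step(
            state,
            config,
            scheme,
            matrix,
            key_id,
            participant_id=participant_id,
            condition=condition,
            block=block,
            round_no=round_no,
        )
        record.label = label.category
        record.optimal = label.optimal_consistent
        records.append(record)
    agent.end_round(state.cumulative_points)
    return records


def play_block(
    agent: Agent,
    config: TaskConfig,
    scheme: TreatmentScheme,
    n_rounds: int,
    rng: int | np.random.Generator,
    *,
    participant_id: str = "",
    condition: str = "",
    block: int = 1,
) -> list[TrialRecord]:
    """Play ``n_rounds`` consecutive rounds under one scheme."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    agent.begin_block(scheme.name)
    records: list[TrialRecord] = []
    for r in range(1, n_rounds + 1):
        records.extend(
            play_round(
                agent,
                config,
                scheme,
                rng,
                participant_id=participant_id,
                condition=condition,
                block=block,
                round_no=r,
            )
        )
    return records
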