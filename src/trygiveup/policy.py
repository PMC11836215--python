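"""Optimal-strategy benchmark: exact belief-state dynamic programming,
a brute-force oracle for small instances, and the per-trial choice classifier.

Because keys within a matrix are i.i.d., an optimal planner never needs
posterior updating over outcome probabilities — only which outcome levels
it has already secured and how many fresh keys remain.  The belief state is
therefore ``(trials_remaining, best_try, best_giveup, unexplored_try,
unexplored_giveup)``, and backward induction over that space is exact.
``brute_force_value`` certifies the abstraction by solving tiny instances
with full per-key histories and no abstraction at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Mapping, NamedTuple

from .task import (
    GIVEUP,
    HIGH,
    LOW,
    TRY,
    ConfigError,
    TaskConfig,
    TreatmentScheme,
)

NONE = "none"
BEST_LEVELS = (NONE, LOW, HIGH)

EXPLORE_TRY = "EXPLORE_TRY"
EXPLORE_GIVEUP = "EXPLORE_GIVEUP"
EXPLOIT_TRY_HIGH = "EXPLOIT_TRY_HIGH"
EXPLOIT_TRY_LOW = "EXPLOIT_TRY_LOW"
EXPLOIT_GIVEUP_HIGH = "EXPLOIT_GIVEUP_HIGH"
EXPLOIT_GIVEUP_LOW = "EXPLOIT_GIVEUP_LOW"

# Fixed preference order used to break exact value ties, so solved policies
# are deterministic and reproducible.
TIE_ORDER = (
    EXPLOIT_TRY_HIGH,
    EXPLORE_TRY,
    EXPLOIT_GIVEUP_HIGH,
    EXPLORE_GIVEUP,
    EXPLOIT_GIVEUP_LOW,
    EXPLOIT_TRY_LOW,
)
_TIE_RANK = {a: i for i, a in enumerate(TIE_ORDER)}

GIVEUP_CAT = "giveup"
TRY_EXPLORE_CAT = "try_explore"
TRY_LOW_EXPLOIT_CAT = "try_low_exploit"
TRY_HIGH_EXPLOIT_CAT = "try_high_exploit"
CATEGORIES = (GIVEUP_CAT, TRY_EXPLORE_CAT, TRY_LOW_EXPLOIT_CAT, TRY_HIGH_EXPLOIT_CAT)


class BeliefState(NamedTuple):
    trials_remaining: int
    best_try: str
    best_giveup: str
    unexplored_try: int
    unexplored_giveup: int


@dataclass(frozen=True)
class ChoiceLabel:
    """Per-trial classification of a choice against the task's categories."""

    category: str
    optimal_consistent: bool


def _check_level_order(config: TaskConfig, scheme: TreatmentScheme) -> None:
    # The best-level abstraction is exact only when a high key never pays
    # less than a low key of the same matrix after scheme deltas.
    for matrix in (TRY, GIVEUP):
        spec = config.spec(matrix)
        eff_high = spec.high_value + scheme.delta(matrix, HIGH)
        eff_low = spec.low_value + scheme.delta(matrix, LOW)
        if eff_high < eff_low:
            raise ConfigError(
                f"scheme {scheme.name!r} inverts the level ordering in the "
                f"{matrix} matrix ({eff_high} < {eff_low}); the belief-state "
                "solver requires high keys to remain weakly better"
            )


class PolicyTable:
    """Solved policy and value function over the belief-state space."""

    def __init__(
        self,
        table: Mapping[BeliefState, tuple[str | None, float]],
        config: TaskConfig,
        scheme_name: str,
    ) -> None:
        self._table = dict(table)
        self.config = config
        self.scheme_name = scheme_name

    def __len__(self) -> int:
        return len(self._table)

    def __iter__(self) -> Iterator[BeliefState]:
        return iter(self._table)

    def action(self, state: BeliefState) -> str | None:
        return self._table[state][0]

    def value(self, state: BeliefState) -> float:
        return self._table[state][1]

    @property
    def root_state(self) -> BeliefState:
        return BeliefState(
            self.config.trials_per_round,
            NONE,
            NONE,
            self.config.try_spec.n_keys,
            self.config.giveup_spec.n_keys,
        )

    @property
    def root_value(self) -> float:
        return self.value(self.root_state)

    def items(self):
        return self._table.items()


def _available_actions(state: BeliefState) -> list[str]:
    acts = []
    if state.best_try == HIGH:
        acts.append(EXPLOIT_TRY_HIGH)
    if state.best_try == LOW:
        acts.append(EXPLOIT_TRY_LOW)
    if state.best_giveup == HIGH:
        acts.append(EXPLOIT_GIVEUP_HIGH)
    if state.best_giveup == LOW:
        acts.append(EXPLOIT_GIVEUP_LOW)
    if state.unexplored_try > 0:
        acts.append(EXPLORE_TRY)
    if state.unexplored_giveup > 0:
        acts.append(EXPLORE_GIVEUP)
    return acts


def _raise_best(best: str, found: str) -> str:
    if best == HIGH or found == HIGH:
        return HIGH
    return LOW


def solve_dp(config: TaskConfig, scheme: TreatmentScheme) -> PolicyTable:
    """Exact finite-horizon backward induction over the belief space.

    The value of a state is the max over available actions of expected
    immediate net payoff (outcome + scheme delta - exploration cost where
    charged) plus the successor value.  Exploration transitions use the
    matrix's ``p_high`` directly; no posterior updating is needed under
    i.i.d. keys.  Exact ties are broken by :data:`TIE_ORDER`.
    """
    _check_level_order(config, scheme)
    t_spec, g_spec = config.try_spec, config.giveup_spec
    nt, ng = t_spec.n_keys, g_spec.n_keys
    pay = {
        EXPLOIT_TRY_HIGH: t_spec.high_value + scheme.delta(TRY, HIGH),
        EXPLOIT_TRY_LOW: t_spec.low_value + scheme.delta(TRY, LOW),
        EXPLOIT_GIVEUP_HIGH: g_spec.high_value + scheme.delta(GIVEUP, HIGH),
        EXPLOIT_GIVEUP_LOW: g_spec.low_value + scheme.delta(GIVEUP, LOW),
    }

    table: dict[BeliefState, tuple[str | None, float]] = {}
    for t in range(config.trials_per_round + 1):
        for bt in BEST_LEVELS:
            for bg in BEST_LEVELS:
                for ut in range(nt + 1):
                    for ug in range(ng + 1):
                        state = BeliefState(t, bt, bg, ut, ug)
                        if t == 0:
                            table[state] = (None, 0.0)
                            continue
                        best: tuple[str | None, float] = (None, 0.0)
                        have_action = False
                        for act in _available_actions(state):
                            if act == EXPLORE_TRY:
                                hi = BeliefState(t - 1, HIGH, bg, ut - 1, ug)
                                lo = BeliefState(
                                    t - 1, _raise_best(bt, LOW), bg, ut - 1, ug
                                )
                                q = -scheme.cost(TRY) + t_spec.p_high * (
                                    pay[EXPLOIT_TRY_HIGH] + table[hi][1]
                                ) + (1.0 - t_spec.p_high) * (
                                    pay[EXPLOIT_TRY_LOW] + table[lo][1]
                                )
                            elif act == EXPLORE_GIVEUP:
                                hi = BeliefState(t - 1, bt, HIGH, ut, ug - 1)
                                lo = BeliefState(
                                    t - 1, bt, _raise_best(bg, LOW), ut, ug - 1
                                )
                                q = -scheme.cost(GIVEUP) + g_spec.p_high * (
                                    pay[EXPLOIT_GIVEUP_HIGH] + table[hi][1]
                                ) + (1.0 - g_spec.p_high) * (
                                    pay[EXPLOIT_GIVEUP_LOW] + table[lo][1]
                                )
                            else:
                                succ = BeliefState(t - 1, bt, bg, ut, ug)
                                q = pay[act] + table[succ][1]
                            if (
                                not have_action
                                or q > best[1]
                                or (q == best[1] and _TIE_RANK[act] < _TIE_RANK[best[0]])
                            ):
                                best = (act, q)
                                have_action = True
                        table[state] = best
    return PolicyTable(table, config, scheme.name)


_BRUTE_MAX_TRIALS = 4
_BRUTE_MAX_KEYS = 3


def brute_force_value(config: TaskConfig, scheme: TreatmentScheme) -> float:
    """Optimal expected round value by exhaustive recursion, no abstraction.

    Tracks the full per-key revealed history of both matrices and maximises
    over every concrete key press, taking expectations over first-press
    outcomes.  Exponential in instance size, so it refuses anything beyond
    4 trials or 3 keys per matrix; it exists purely as an independent
    oracle for :func:`solve_dp`.
    """
    if config.trials_per_round > _BRUTE_MAX_TRIALS:
        raise ValueError("brute force restricted to trials_per_round <= 4")
    if max(config.try_spec.n_keys, config.giveup_spec.n_keys) > _BRUTE_MAX_KEYS:
        raise ValueError("brute force restricted to <= 3 keys per matrix")

    specs = {TRY: config.try_spec, GIVEUP: config.giveup_spec}

    @lru_cache(maxsize=None)
    def value(t: int, try_keys: tuple, gu_keys: tuple) -> float:
        if t == 0:
            return 0.0
        keys = {TRY: try_keys, GIVEUP: gu_keys}
        best = None
        for matrix in (TRY, GIVEUP):
            spec = specs[matrix]
            for k, level in enumerate(keys[matrix]):
                if level is not None:  # exploit a revealed key
                    q = (
                        spec.value(level)
                        + scheme.delta(matrix, level)
                        + value(t - 1, try_keys, gu_keys)
                    )
                else:  # first press: expectation over the latent outcome
                    q = -scheme.cost(matrix)
                    for lvl, p in ((HIGH, spec.p_high), (LOW, 1.0 - spec.p_high)):
                        if p == 0.0:
                            continue
                        new = list(keys[matrix])
                        new[k] = lvl
                        if matrix == TRY:
                            succ = value(t - 1, tuple(new), gu_keys)
                        else:
                            succ = value(t - 1, try_keys, tuple(new))
                        q += p * (spec.value(lvl) + scheme.delta(matrix, lvl) + succ)
                if best is None or q > best:
                    best = q
        return best if best is not None else 0.0

    return value(
        config.trials_per_round,
        (None,) * config.try_spec.n_keys,
        (None,) * config.giveup_spec.n_keys,
    )


def classify_choice(
    revealed: Mapping[str, Mapping[int, str]], matrix: str, key_id: int
) -> ChoiceLabel:
    """Classify one choice given the revealed state before the trial.

    Categories partition all choices: any Give-Up press is ``giveup``; a
    fresh Try press is ``try_explore``; re-pressing a revealed Try key is
    ``try_low_exploit`` or ``try_high_exploit`` by its revealed level.

    A choice is consistent with the optimal benchmark iff either no high
    Try key is known and the choice explores a fresh Try key, or a high
    Try key is known and the choice exploits a known-high Try key.
    """
    revealed_try = revealed[TRY]
    high_known = HIGH in revealed_try.values()
    if matrix == GIVEUP:
        return ChoiceLabel(GIVEUP_CAT, False)
    if matrix != TRY:
        raise ValueError(f"unknown matrix {matrix!r}")
    level = revealed_try.get(key_id)
    if level is None:
        return ChoiceLabel(TRY_EXPLORE_CAT, not high_known)
    if level == HIGH:
        return ChoiceLabel(TRY_HIGH_EXPLOIT_CAT, True)
    return ChoiceLabel(TRY_LOW_EXPLOIT_CAT, False)
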