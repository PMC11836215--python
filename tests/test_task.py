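import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trygiveup import (
    SCHEMES,
    ConfigError,
    MatrixSpec,
    StateError,
    TaskConfig,
    apply_scheme,
    get_scheme,
    sample_round,
    step,
)
from trygiveup.task import GIVEUP, HIGH, LOW, TRY


class TestSchemeTable:
    """The five schemes reproduce the shipped incentive design cell by cell."""

    @pytest.mark.parametrize(
        "scheme,matrix,level,first,delta,displayed",
        [
            ("minus_giveup", GIVEUP, HIGH, False, -2.0, 0.0),
            ("minus_giveup", GIVEUP, LOW, False, -2.0, -1.0),
            ("minus_giveup", TRY, HIGH, False, 0.0, 14.0),
            ("plus_try", TRY, LOW, False, 2.0, 3.0),
            ("plus_try", TRY, HIGH, False, 2.0, 16.0),
            ("plus_try", GIVEUP, HIGH, False, 0.0, 2.0),
            ("minus_giveup_minus_trylow", TRY, LOW, False, -2.0, -1.0),
            ("minus_giveup_minus_trylow", TRY, HIGH, False, 0.0, 14.0),
            ("minus_giveup_minus_trylow", GIVEUP, LOW, False, -2.0, -1.0),
            ("baseline", TRY, HIGH, False, 0.0, 14.0),
        ],
    )
    def test_outcome_deltas(self, config, scheme, matrix, level, first, delta, displayed):
        d, _ = apply_scheme(get_scheme(scheme), matrix, level, first)
        assert d == delta
        assert config.spec(matrix).value(level) + d == displayed

    @pytest.mark.parametrize(
        "scheme,matrix,cost",
        [
            ("baseline", TRY, 2.0),
            ("baseline", GIVEUP, 2.0),
            ("plus_try_explore", TRY, 0.0),
            ("plus_try_explore", GIVEUP, 2.0),
            ("minus_giveup", TRY, 2.0),
        ],
    )
    def test_exploration_costs_on_first_press(self, scheme, matrix, cost):
        _, charged = apply_scheme(get_scheme(scheme), matrix, HIGH, first_press=True)
        assert charged == cost
        _, charged = apply_scheme(get_scheme(scheme), matrix, HIGH, first_press=False)
        assert charged == 0.0

    def test_baseline_try_high_first_press_nets_twelve(self, config, baseline):
        d, c = apply_scheme(baseline, TRY, HIGH, True)
        assert config.try_spec.high_value + d - c == 12.0

    def test_unknown_scheme_is_config_error(self):
        with pytest.raises(ConfigError, match="unknown scheme"):
            get_scheme("double_giveup")


class TestSampleRound:
    def test_degenerate_probabilities(self):
        cfg = TaskConfig(try_spec=MatrixSpec(1, 14, 1.0, 12))
        state = sample_round(cfg, 0)
        assert all(lvl == HIGH for lvl in state.latent_levels[TRY])
        cfg = TaskConfig(try_spec=MatrixSpec(1, 14, 0.0, 12))
        state = sample_round(cfg, 0)
        assert all(lvl == LOW for lvl in state.latent_levels[TRY])

    def test_fresh_round_reveals_nothing(self, config):
        state = sample_round(config, 3)
        assert state.revealed == {TRY: {}, GIVEUP: {}}
        assert state.trial_index == 1

    def test_bit_reproducible_for_fixed_seed(self, config):
        a = sample_round(config, 42)
        b = sample_round(config, 42)
        assert a.latent_levels == b.latent_levels

    def test_high_key_count_matches_binomial_expectation(self, config):
        # 12 keys at p=.1: mean 1.2 high Try keys per round, sd sqrt(12*.1*.9)
        n = 10_000
        rng = np.random.default_rng(7)
        counts = [
            sum(lvl == HIGH for lvl in sample_round(config, rng).latent_levels[TRY])
            for _ in range(n)
        ]
        se = np.sqrt(12 * 0.1 * 0.9 / n)
        assert abs(np.mean(counts) - 1.2) < 3 * se


class TestStep:
    def test_first_press_giveup_high_nets_zero_at_baseline(self, config, baseline):
        cfg = TaskConfig(giveup_spec=MatrixSpec(1, 2, 1.0, 12))
        state = sample_round(cfg, 0)
        rec, state = step(state, cfg, baseline, GIVEUP, 0)
        assert rec.first_press and rec.raw_outcome == 2.0 and rec.net_points == 0.0

    def test_second_press_costs_nothing(self, baseline):
        cfg = TaskConfig(try_spec=MatrixSpec(1, 14, 0.0, 12))
        state = sample_round(cfg, 0)
        _, state = step(state, cfg, baseline, TRY, 5)
        rec, state = step(state, cfg, baseline, TRY, 5)
        assert not rec.first_press and rec.cost_charged == 0.0 and rec.net_points == 1.0

    def test_plus_try_explore_negates_cost_on_fresh_try_high(self):
        cfg = TaskConfig(try_spec=MatrixSpec(1, 14, 1.0, 12))
        state = sample_round(cfg, 0)
        rec, _ = step(state, cfg, get_scheme("plus_try_explore"), TRY, 0)
        assert rec.first_press and rec.cost_charged == 0.0 and rec.net_points == 14.0

    def test_step_past_round_end_raises(self, config, baseline):
        state = sample_round(config, 0)
        for _ in range(config.trials_per_round):
            _, state = step(state, config, baseline, GIVEUP, 0)
        with pytest.raises(StateError):
            step(state, config, baseline, GIVEUP, 0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        seed=st.integers(0, 2**31 - 1),
        scheme_name=st.sampled_from(sorted(SCHEMES)),
        data=st.data(),
    )
    def test_decomposition_identity_and_fixed_outcomes(self, seed, scheme_name, data):
        """net = raw + delta - cost on every record; revealed keys never change."""
        cfg = TaskConfig()
        scheme = get_scheme(scheme_name)
        state = sample_round(cfg, seed)
        seen: dict[tuple[str, int], float] = {}
        for _ in range(cfg.trials_per_round):
            matrix = data.draw(st.sampled_from([TRY, GIVEUP]))
            key = data.draw(st.integers(0, 11))
            rec, state = step(state, cfg, scheme, matrix, key)
            assert rec.net_points == rec.raw_outcome + rec.scheme_delta - rec.cost_charged
            assert rec.cost_charged == 0.0 or rec.first_press
            if (matrix, key) in seen:
                assert rec.raw_outcome == seen[(matrix, key)]
                assert not rec.first_press
            seen[(matrix, key)] = rec.raw_outcome


class TestSchemeRoundTrip:
    @pytest.mark.parametrize("scheme_name", sorted(set(SCHEMES) - {"baseline"}))
    def test_baseline_replay_equals_scheme_minus_adjustments(self, scheme_name, config, baseline):
        """Replaying a fixed choice sequence: baseline nets equal scheme nets
        minus the scheme's deltas plus the cost differences, exactly."""
        scheme = get_scheme(scheme_name)
        rng = np.random.default_rng(11)
        for trial_seed in rng.integers(0, 2**31 - 1, size=20):
            choices = [
                (TRY if rng.random() < 0.5 else GIVEUP, int(rng.integers(0, 12)))
                for _ in range(config.trials_per_round)
            ]
            s1 = sample_round(config, int(trial_seed))
            s2 = sample_round(config, int(trial_seed))
            for matrix, key in choices:
                r_scheme, s1 = step(s1, config, scheme, matrix, key)
                r_base, s2 = step(s2, config, baseline, matrix, key)
                assert r_base.raw_outcome == r_scheme.raw_outcome
                adjustment = r_scheme.scheme_delta - (
                    r_scheme.cost_charged - r_base.cost_charged
                )
                assert r_base.net_points == r_scheme.net_points - adjustment


class TestValidation:
    def test_probability_out_of_range(self):
        with pytest.raises(ConfigError, match="p_high"):
            MatrixSpec(1, 14, 1.5, 12)

    def test_inverted_values(self):
        with pytest.raises(ConfigError, match="high_value"):
            MatrixSpec(5, 1, 0.5, 12)

    def test_window_wider_than_round(self):
        with pytest.raises(ConfigError, match="analysis_window"):
            TaskConfig(analysis_window=13)

    def test_negative_exploration_cost(self):
        from trygiveup import TreatmentScheme

        with pytest.raises(ConfigError, match="cost"):
            TreatmentScheme("bad", {}, {TRY: -1.0})
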