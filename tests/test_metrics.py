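import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from trygiveup import (
    AgentSpec,
    TaskConfig,
    anova_oneway,
    category_shares,
    compute_rates,
    difference_scores,
    dv_correlation,
    get_scheme,
    label_log,
    make_agent,
    play_round,
    strip_incentives,
)
from trygiveup.metrics import SchemaError
from trygiveup.task import GIVEUP, TRY


def log_from_rounds(records):
    frame = pd.DataFrame([vars(r) for r in records])
    frame["first_press"] = frame["first_press"].astype(int)
    frame["optimal"] = frame["optimal"].astype(int)
    return frame


def hand_log(choices, participant="P1", block=1, round_no=1, condition="c", cfg=None):
    """Build a minimal labeled log by stepping the simulator through choices."""
    from trygiveup import MatrixSpec, sample_round, step
    from trygiveup.policy import classify_choice

    # all Try keys low by default so fresh explorations stay benchmark-optimal
    cfg = cfg or TaskConfig(try_spec=MatrixSpec(1, 14, 0.0, 12))
    scheme = get_scheme("baseline")
    state = sample_round(cfg, 0)
    records = []
    for matrix, key in choices:
        lab = classify_choice({m: dict(state.revealed[m]) for m in (TRY, GIVEUP)}, matrix, key)
        rec, state = step(
            state, cfg, scheme, matrix, key,
            participant_id=participant, condition=condition,
            block=block, round_no=round_no,
        )
        rec.label = lab.category
        rec.optimal = lab.optimal_consistent
        records.append(rec)
    return log_from_rounds(records)


class TestComputeRates:
    def test_counting_example(self):
        # 3 Give-Up choices and 6 fresh Try explorations in the window:
        # giveup 1/3, trylow 0, optimal 2/3
        choices = [(GIVEUP, k) for k in range(3)] + [(TRY, k) for k in range(6)]
        choices += [(TRY, 0)] * 3  # outside the 9-trial window
        log = hand_log(choices)
        rows = compute_rates(log, window=9)
        assert len(rows) == 1
        r = rows.iloc[0]
        assert r["giveup_rate"] == pytest.approx(1 / 3)
        assert r["trylow_rate"] == 0.0
        assert r["optimal_rate"] == pytest.approx(2 / 3)
        assert r["n_trials"] == 9

    def test_window_widening_changes_denominator(self):
        choices = [(GIVEUP, k) for k in range(3)] + [(TRY, k) for k in range(9)]
        log = hand_log(choices)
        r9 = compute_rates(log, window=9).iloc[0]
        r12 = compute_rates(log, window=12).iloc[0]
        assert r9["n_trials"] == 9 and r12["n_trials"] == 12
        assert r9["giveup_rate"] == pytest.approx(3 / 9)
        assert r12["giveup_rate"] == pytest.approx(3 / 12)

    def test_all_optimal_log(self, config, baseline):
        agent = make_agent(AgentSpec("threshold_try", {"m": 12}), config)
        log = log_from_rounds(play_round(agent, config, baseline, 3))
        r = compute_rates(log, window=9).iloc[0]
        assert r["optimal_rate"] == 1.0 and r["giveup_rate"] == 0.0

    def test_labels_recomputed_when_missing(self, config, baseline):
        agent = make_agent(AgentSpec("threshold_try", {"m": 12}), config)
        log = log_from_rounds(play_round(agent, config, baseline, 3))
        stripped = log.drop(columns=["label", "optimal"])
        relabeled = label_log(stripped, config)
        assert list(relabeled["label"]) == list(log["label"])
        assert list(relabeled["optimal"]) == list(log["optimal"])

    def test_malformed_log_rejected_with_row_index(self):
        log = hand_log([(TRY, 0)])
        log.loc[0, "matrix"] = "maybe"
        with pytest.raises(SchemaError, match="row 0"):
            compute_rates(log)


class TestStripIncentives:
    def test_scheme_examples(self):
        from trygiveup import MatrixSpec, sample_round, step

        cfg = TaskConfig(try_spec=MatrixSpec(1, 14, 0.0, 12))
        # +Try: second press of a low Try key displays +3, strips to +1
        state = sample_round(cfg, 0)
        recs = []
        for _ in range(2):
            rec, state = step(state, cfg, get_scheme("plus_try"), TRY, 0)
            recs.append(rec)
        log = strip_incentives(log_from_rounds(recs), cfg)
        assert log.loc[1, "net_points"] == 3.0
        assert log.loc[1, "net_points_stripped"] == 1.0
        # +Try_Explore: first Try press of a low key nets +1, strips to -1
        state = sample_round(cfg, 0)
        rec, _ = step(state, cfg, get_scheme("plus_try_explore"), TRY, 0)
        log = strip_incentives(log_from_rounds([rec]), cfg)
        assert log.loc[0, "net_points"] == 1.0
        assert log.loc[0, "net_points_stripped"] == -1.0

    def test_baseline_log_unchanged(self, config, baseline):
        agent = make_agent(AgentSpec("threshold_try", {"m": 12}), config)
        log = strip_incentives(log_from_rounds(play_round(agent, config, baseline, 9)), config)
        assert (log["net_points_stripped"] == log["net_points"]).all()

    @pytest.mark.parametrize("scheme_name", ["minus_giveup", "plus_try", "plus_try_explore"])
    def test_stripping_equals_baseline_replay(self, config, baseline, scheme_name):
        """Stripped payoffs equal a baseline replay of the identical choices."""
        from trygiveup import sample_round, step

        scheme = get_scheme(scheme_name)
        rng = np.random.default_rng(17)
        for seed in rng.integers(0, 2**31 - 1, size=25):
            choices = [
                (TRY if rng.random() < 0.5 else GIVEUP, int(rng.integers(0, 12)))
                for _ in range(12)
            ]
            s1, s2 = sample_round(config, int(seed)), sample_round(config, int(seed))
            treat, base = [], []
            for matrix, key in choices:
                r1, s1 = step(s1, config, scheme, matrix, key)
                r2, s2 = step(s2, config, baseline, matrix, key)
                treat.append(r1)
                base.append(r2)
            stripped = strip_incentives(log_from_rounds(treat), config)
            assert list(stripped["net_points_stripped"]) == [r.net_points for r in base]


class TestAnova:
    def test_hand_computed_example(self):
        # groups [1,2,3], [2,3,4], [6,7,8]: SSb=42 (df 2), SSw=6 (df 6) -> F=21
        res = anova_oneway([[1, 2, 3], [2, 3, 4], [6, 7, 8]])
        assert res.F == pytest.approx(21.0)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.p == pytest.approx(stats.f.sf(21.0, 2, 6))

    def test_agrees_with_library_implementation(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(loc, 1.0, size=20) for loc in (0.0, 0.3, 0.1)]
        ours = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert ours.F == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue)

    def test_degenerate_groups_report_infinite_f_with_warning(self):
        with pytest.warns(RuntimeWarning, match="infinite"):
            res = anova_oneway([[0, 0, 0], [1, 1, 1]])
        assert np.isinf(res.F) and res.p == 0.0

    def test_tiny_groups_refused(self):
        with pytest.raises(ValueError, match="refused"):
            anova_oneway([[1], [2, 3]])


class TestDifferenceScores:
    @staticmethod
    def rows_from(values):
        out = []
        for pid, cond, block, gu in values:
            out.append(
                dict(participant_id=pid, condition=cond, block=block,
                     giveup_rate=gu, trylow_rate=0.1, optimal_rate=1 - gu,
                     mean_payoff=2.0, mean_payoff_stripped=2.0)
            )
        return pd.DataFrame(out)

    def test_identical_blocks_give_zero_centered_cis(self):
        rows = self.rows_from(
            [(p, "c", b, g) for p, g in [("P1", 0.4), ("P2", 0.6), ("P3", 0.5)]
             for b in (1, 2, 3)]
        )
        diffs = difference_scores(rows)
        gu = diffs[diffs["dv"] == "giveup_rate"]
        assert (gu["mean"] == 0).all()
        assert (gu["ci_low"] <= 0).all() and (gu["ci_high"] >= 0).all()

    def test_ci_contains_mean_and_scales_rates_to_percent(self):
        rows = self.rows_from(
            [("P1", "c", 1, 0.5), ("P1", "c", 2, 0.2), ("P1", "c", 3, 0.5),
             ("P2", "c", 1, 0.6), ("P2", "c", 2, 0.4), ("P2", "c", 3, 0.6)]
        )
        diffs = difference_scores(rows)
        row = diffs[(diffs["dv"] == "giveup_rate") & (diffs["contrast"] == "treatment")].iloc[0]
        assert row["mean"] == pytest.approx(-25.0)  # mean of -30 and -20 pct points
        assert row["ci_low"] <= row["mean"] <= row["ci_high"]

    def test_bootstrap_ci_available(self):
        rows = self.rows_from(
            [(f"P{i}", "c", b, 0.5 + 0.01 * i * (b - 1)) for i in range(8) for b in (1, 2, 3)]
        )
        diffs = difference_scores(rows, ci_method="bootstrap", rng=0)
        row = diffs[(diffs["dv"] == "giveup_rate") & (diffs["contrast"] == "treatment")].iloc[0]
        assert row["ci_low"] <= row["mean"] <= row["ci_high"]

    def test_single_participant_condition_warns(self):
        rows = self.rows_from([("P1", "solo", b, 0.5) for b in (1, 2, 3)])
        with pytest.warns(RuntimeWarning, match="CI not computed"):
            diffs = difference_scores(rows)
        assert diffs["ci_low"].isna().all()


class TestCorrelation:
    def test_perfect_anticorrelation_is_clamped_finite(self):
        rows = TestDifferenceScores.rows_from(
            [(f"P{i}", c, b, 0.1 * i) for i in range(5) for b in (1, 2) for c in ("a", "b")]
        )
        res = dv_correlation(rows)
        for r in res.by_condition.values():
            assert r == pytest.approx(-1.0)
        assert np.isfinite(res.fisher_z_mean)
        assert res.mean_r == pytest.approx(-1.0)

    def test_default_cohort_correlation_is_negative(self, cohort_rates):
        res = dv_correlation(cohort_rates)
        assert all(r < 0 for r in res.by_condition.values())
        assert res.mean_r < 0


class TestCategoryShares:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_shares_sum_to_one_on_random_logs(self, seed):
        cfg = TaskConfig()

        class RandomAgent:
            def begin_round(self, rng):
                pass

            def end_round(self, payoff):
                pass

            def begin_block(self, scheme):
                pass

            def choose(self, view, rng):
                matrix = TRY if rng.random() < 0.5 else GIVEUP
                return matrix, int(rng.integers(0, 12))

        log = log_from_rounds(
            play_round(RandomAgent(), cfg, get_scheme("baseline"), seed)
        )
        shares = category_shares(log, window=9)
        assert np.allclose(shares.sum(axis=1), 1.0)
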