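
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dualcontrol import (
    DevalSession,
    StayTable,
    TwoStepSession,
    UndefinedScoreError,
    ValidationError,
    deval_choice_counts,
    deval_interaction_score,
    mb_interaction_score,
    reward_and_interaction_contrasts,
    reward_main_effect_score,
    spearman_onetailed,
    stay_table,
)
from dualcontrol.devaluation import CONDITIONS, DevalTrial


def table(rc, rr, uc, ur, n=25):
    return StayTable(p_stay=np.array([[rc, rr], [uc, ur]]), n=np.full((2, 2), n))


class TestStayTable:
    def test_hand_tally_three_trials(self, structure, walk3):
        # previous-trial (reward, transition) pairs: (1, common), (0, rare)
        session = TwoStepSession.from_arrays(
            "s", a1=[0, 0, 1], s2=[0, 1, 0], a2=[0, 0, 0], r=[1, 0, 0],
            structure=structure, walk=walk3,
        )
        tab = stay_table(session)
        assert tab.cell(rewarded=True, common=True) == 1.0
        assert tab.cell(rewarded=False, common=False) == 0.0
        assert tab.n[0, 1] == 0 and tab.n[1, 0] == 0
        assert np.isnan(tab.p_stay[0, 1]) and np.isnan(tab.p_stay[1, 0])

    def test_constant_chooser_always_stays(self, structure):
        rng = np.random.default_rng(0)
        n = 50
        a1 = np.zeros(n, int)
        s2 = rng.integers(0, 2, n)
        session = TwoStepSession.from_arrays(
            "c", a1, s2, rng.integers(0, 2, n), rng.integers(0, 2, n), structure=structure
        )
        tab = stay_table(session)
        assert np.all(tab.p_stay[tab.n > 0] == 1.0)

    def test_alternating_chooser_never_stays(self, structure):
        rng = np.random.default_rng(1)
        n = 50
        a1 = np.arange(n) % 2
        session = TwoStepSession.from_arrays(
            "a", a1, rng.integers(0, 2, n), rng.integers(0, 2, n),
            rng.integers(0, 2, n), structure=structure,
        )
        tab = stay_table(session)
        assert np.all(tab.p_stay[tab.n > 0] == 0.0)

    def test_single_trial_session_rejected(self, structure, walk3):
        session = TwoStepSession.from_arrays("x", [0], [0], [0], [0], structure=structure)
        with pytest.raises(ValidationError):
            stay_table(session)


class TestInteractionScore:
    def test_hand_arithmetic(self):
        assert mb_interaction_score(table(0.9, 0.6, 0.6, 0.9)) == pytest.approx(0.6)

    def test_flat_table_scores_zero(self):
        assert mb_interaction_score(table(0.7, 0.7, 0.7, 0.7)) == 0.0

    def test_pure_main_effect_scores_zero(self):
        assert mb_interaction_score(table(0.9, 0.9, 0.5, 0.5)) == 0.0

    def test_missing_cell_is_an_error(self):
        t = StayTable(
            p_stay=np.array([[0.9, np.nan], [0.5, 0.5]]),
            n=np.array([[5, 0], [5, 5]]),
        )
        with pytest.raises(UndefinedScoreError):
            mb_interaction_score(t)
        with pytest.raises(UndefinedScoreError):
            reward_main_effect_score(t)

    @given(shift=st.floats(-0.3, 0.3))
    def test_invariant_under_constant_shift(self, shift):
        base = table(0.9, 0.6, 0.55, 0.8)
        shifted = StayTable(p_stay=base.p_stay + shift, n=base.n)
        assert mb_interaction_score(shifted) == pytest.approx(
            mb_interaction_score(base), abs=1e-12
        )

    def test_sign_flips_when_transition_labels_swap(self):
        base = table(0.9, 0.6, 0.55, 0.8)
        swapped = StayTable(p_stay=base.p_stay[:, ::-1], n=base.n)
        assert mb_interaction_score(swapped) == pytest.approx(
            -mb_interaction_score(base), abs=1e-12
        )


class TestGroupContrasts:
    def test_null_data_gives_zero_contrasts(self):
        tables = [table(0.7, 0.7, 0.7, 0.7) for _ in range(5)]
        main, inter = reward_and_interaction_contrasts(tables)
        assert main.mean == 0.0 and inter.mean == 0.0
        assert main.F == 0.0 and inter.F == 0.0

    def test_f_equals_t_squared_and_df(self):
        rng = np.random.default_rng(3)
        tables = [table(*rng.uniform(0.2, 0.95, 4)) for _ in range(12)]
        for c in reward_and_interaction_contrasts(tables):
            assert c.F == pytest.approx(c.t**2, abs=1e-10)
            assert c.df == (1, 11)

    def test_matches_independent_repeated_measures_anova(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(4)
        tables = [table(*rng.uniform(0.2, 0.95, 4)) for _ in range(4)]
        rows = []
        for sid, t in enumerate(tables):
            for i, reward in enumerate(["yes", "no"]):
                for j, trans in enumerate(["common", "rare"]):
                    rows.append(
                        {"subject": sid, "reward": reward, "transition": trans,
                         "stay": t.p_stay[i, j]}
                    )
        res = AnovaRM(
            pd.DataFrame(rows), depvar="stay", subject="subject",
            within=["reward", "transition"],
        ).fit()
        main, inter = reward_and_interaction_contrasts(tables)
        assert main.F == pytest.approx(res.anova_table.loc["reward", "F Value"], abs=1e-8)
        assert inter.F == pytest.approx(
            res.anova_table.loc["reward:transition", "F Value"], abs=1e-8
        )
        assert main.p == pytest.approx(res.anova_table.loc["reward", "Pr > F"], abs=1e-8)

    def test_incomplete_subjects_dropped(self):
        good = [table(0.9, 0.6, 0.5, 0.8) for _ in range(3)]
        bad = StayTable(
            p_stay=np.array([[0.9, np.nan], [0.5, 0.5]]), n=np.array([[5, 0], [5, 5]])
        )
        main_all, _ = reward_and_interaction_contrasts(good + [bad])
        main_good, _ = reward_and_interaction_contrasts(good)
        assert main_all == main_good

    def test_too_few_complete_subjects_rejected(self):
        with pytest.raises(ValidationError):
            reward_and_interaction_contrasts([table(0.9, 0.6, 0.5, 0.8)] * 2)


def build_deval_session(per_condition_choices):
    """per_condition_choices: {condition: (training choices, extinction choices)}"""
    trials = []
    for phase_idx, phase in enumerate(["training", "extinction"]):
        for cond, seqs in per_condition_choices.items():
            for t, ch in enumerate(seqs[phase_idx], start=1):
                trials.append(
                    DevalTrial(t=t, phase=phase, condition=cond, choice=ch, outcome="none")
                )
    return DevalSession("manual", "chocolate", trials)


class TestDevalCounts:
    def test_ceiling_agent_fills_every_cell(self):
        session = build_deval_session(
            {c: (["high"] * 50, ["high"] * 50) for c in CONDITIONS}
        )
        counts = deval_choice_counts(session)
        assert (counts.to_numpy() == 10).all()

    def test_hand_tallied_fixture(self):
        choices = {
            "devalued": (["low"] * 41 + ["high"] * 9, ["high"] * 2 + ["low"] * 48),
            "valued": (["low"] * 42 + ["high"] * 8, ["high"] * 8 + ["low"] * 42),
            "neutral": (["high"] * 50, ["low"] * 50),
        }
        counts = deval_choice_counts(build_deval_session(choices))
        assert counts.loc["pre", "devalued"] == 9
        assert counts.loc["post", "devalued"] == 2
        assert counts.loc["pre", "valued"] == 8
        assert counts.loc["post", "valued"] == 8
        assert counts.loc["pre", "neutral"] == 10
        assert counts.loc["post", "neutral"] == 0

    def test_window_exceeding_phase_length_rejected(self):
        session = build_deval_session({c: (["high"] * 5, ["high"] * 5) for c in CONDITIONS})
        with pytest.raises(ValidationError):
            deval_choice_counts(session, window=10)


class TestDevalScore:
    def counts(self, dev_pre, dev_post, val_pre, val_post):
        return pd.DataFrame(
            {"devalued": [dev_pre, dev_post], "valued": [val_pre, val_post],
             "neutral": [10, 10]},
            index=["pre", "post"],
        )

    def test_goal_directed_pattern_is_positive_by_default(self):
        c = self.counts(9, 2, 8, 8)
        assert deval_interaction_score(c) == 7.0
        assert deval_interaction_score(c, literal_formula=True) == -7.0

    def test_no_change_scores_zero(self):
        c = self.counts(9, 9, 8, 8)
        assert deval_interaction_score(c) == 0.0
        assert deval_interaction_score(c, literal_formula=True) == 0.0

    def test_condition_nonspecific_extinction_cancels(self):
        assert deval_interaction_score(self.counts(9, 5, 8, 4)) == 0.0


class TestSpearman:
    def test_perfect_monotone_n5_exact_permutation(self):
        rho, p = spearman_onetailed([1, 2, 3, 4, 5], [10, 20, 40, 80, 160])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 120, abs=1e-12)

    def test_perfect_anticorrelation(self):
        rho, p = spearman_onetailed([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_rho_with_ties(self):
        from scipy import stats

        x = [1.0, 2.0, 2.0, 3.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 2.5]
        y = [2.0, 1.0, 4.0, 4.0, 4.0, 7.0, 6.0, 9.0, 8.0, 12.0, 11.0, 3.0]
        rho, _ = spearman_onetailed(x, y)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_invariant_under_monotone_transforms(self):
        x = [0.3, 1.2, 2.0, 2.7, 5.5, 7.1]
        y = [1.0, 0.4, 2.2, 3.3, 2.9, 6.0]
        rho, p = spearman_onetailed(x, y)
        rho2, p2 = spearman_onetailed(np.exp(x), np.log(np.asarray(y) + 1.0))
        assert rho2 == pytest.approx(rho, abs=1e-12)
        assert p2 == pytest.approx(p, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedScoreError):
            spearman_onetailed([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            spearman_onetailed([1, 2, 3], [1, 2, 3])

    def test_null_calibration_at_n13(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_sims = 2000
        for _ in range(n_sims):
            _, p = spearman_onetailed(rng.standard_normal(13), rng.standard_normal(13))
            rejections += p < 0.05
        assert rejections / n_sims == pytest.approx(0.05, abs=0.02)
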