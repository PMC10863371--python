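import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twostep.stats import (
    EmptyCellError,
    StayTable,
    cohort_staytables,
    exclusion_filter,
    intervention_analysis,
    mb_effect,
    mf_effect,
    rm_anova_oneway,
    stay_table,
)

unit = st.floats(0.0, 1.0)


def make_table(pcp, prp, pcm, prm, n=10):
    return StayTable(
        p_com_plus=pcp, p_rar_plus=prp, p_com_minus=pcm, p_rar_minus=prm,
        n_com_plus=n, n_rar_plus=n, n_com_minus=n, n_rar_minus=n,
    )


def session_df(rows):
    """rows: (choice1, transition, reward) or None for a missing trial;
    state2/choice2 filled consistently."""
    from twostep.task import COMMON

    out = []
    for t, row in enumerate(rows):
        if row is None:
            out.append((t, pd.NA, pd.NA, pd.NA, pd.NA, 0, True))
        else:
            c1, tr, r = row
            s2 = c1 if tr == COMMON else 1 - c1
            out.append((t, c1, s2, 0, tr, r, False))
    df = pd.DataFrame(
        out, columns=["trial", "choice1", "state2", "choice2", "transition", "reward", "missing"]
    )
    for col in ("choice1", "state2", "choice2"):
        df[col] = df[col].astype("Int64")
    return df


class TestStayTable:
    def test_hand_enumerated_12_trial_fixture(self):
        from twostep.task import COMMON as C
        from twostep.task import RARE as R

        rows = [
            (0, C, 1),  # -> stay     (+, com)
            (0, C, 0),  # -> switch   (-, com)
            (1, R, 1),  # -> switch   (+, rar)
            (0, R, 0),  # -> stay     (-, rar)
            (0, C, 1),  # -> switch   (+, com)
            (1, C, 0),  # -> stay     (-, com)
            (1, R, 1),  # -> stay     (+, rar)
            (1, R, 0),  # next missing: pair dropped
            None,
            (0, C, 1),  # -> stay     (+, com)
            (0, R, 0),  # -> switch   (-, rar)
            (1, C, 1),  # last trial: no pair
        ]
        tab = stay_table(session_df(rows))
        assert (tab.n_com_plus, tab.n_com_minus, tab.n_rar_plus, tab.n_rar_minus) == (3, 2, 2, 2)
        assert tab.p_com_plus == pytest.approx(2 / 3)
        assert tab.p_com_minus == pytest.approx(1 / 2)
        assert tab.p_rar_plus == pytest.approx(1 / 2)
        assert tab.p_rar_minus == pytest.approx(1 / 2)
        assert tab.mf_effect == pytest.approx(1 / 12)
        assert tab.mb_effect == pytest.approx(1 / 12)

    def test_single_pair_contributes_to_correct_cell(self):
        from twostep.task import COMMON as C

        tab = stay_table(session_df([(0, C, 1), (0, C, 1)]))
        assert tab.n_com_plus == 1 and tab.p_com_plus == 1.0
        assert "rar_plus" in tab.flagged_cells

    def test_constant_chooser_degenerate(self):
        from twostep.task import COMMON as C
        from twostep.task import RARE as R

        rows = [(0, C, 1), (0, C, 0), (0, R, 1), (0, R, 0)] * 3
        tab = stay_table(session_df(rows))
        for cell in ("p_com_plus", "p_rar_plus", "p_com_minus", "p_rar_minus"):
            assert getattr(tab, cell) == 1.0
        assert tab.mf_effect == 0.0 and tab.mb_effect == 0.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="all trials missing"):
            stay_table(session_df([None, None]))

    def test_empty_cell_blocks_effects(self):
        tab = StayTable(1.0, float("nan"), 1.0, 1.0, 2, 0, 2, 2)
        assert tab.flagged_cells == ("rar_plus",)
        with pytest.raises(EmptyCellError):
            mf_effect(tab)


class TestEffects:
    def test_pure_reward_main_effect(self):
        tab = make_table(0.8, 0.8, 0.6, 0.6)
        assert mf_effect(tab) == pytest.approx(0.2)
        assert mb_effect(tab) == pytest.approx(0.0)

    def test_pure_interaction(self):
        tab = make_table(0.9, 0.5, 0.5, 0.9)
        assert mf_effect(tab) == pytest.approx(0.0)
        assert mb_effect(tab) == pytest.approx(0.4)

    def test_null_pattern(self):
        tab = make_table(0.5, 0.5, 0.5, 0.5)
        assert mf_effect(tab) == 0.0 and mb_effect(tab) == 0.0

    @given(unit, unit, unit, unit)
    @settings(max_examples=200, deadline=None)
    def test_algebraic_identities(self, pcp, prp, pcm, prm):
        tab = make_table(pcp, prp, pcm, prm)
        mf, mb = mf_effect(tab), mb_effect(tab)
        assert mf + mb == pytest.approx(pcp - pcm, abs=1e-12)
        assert mf - mb == pytest.approx(prp - prm, abs=1e-12)
        assert -1.0 <= mf <= 1.0 and -1.0 <= mb <= 1.0


def cohort_with_missing(missing_counts, n_trials=201):
    """One-subject-per-entry cohort; missing_counts[sid][cond] = #missing."""
    frames = []
    for sid, conds in missing_counts.items():
        for cond, k in conds.items():
            df = session_df([(0, "common", 1)] * n_trials)
            df.loc[: k - 1, "missing"] = k > 0
            if k > 0:
                df.loc[: k - 1, ["choice1", "state2", "choice2"]] = pd.NA
            df.insert(0, "subject_id", sid)
            df.insert(1, "intervention", cond)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestExclusionFilter:
    def test_over_threshold_excluded(self):
        # 61/201 = 30.35% > 30% in one session -> subject excluded entirely
        trials = cohort_with_missing({"A": {"ATD": 61, "BAL": 0, "ATL": 0}})
        kept, log = exclusion_filter(trials)
        assert kept.empty
        assert log.iloc[0]["missing_fraction"] == pytest.approx(61 / 201)

    def test_under_threshold_retained(self):
        # 60/201 = 29.85% in every session -> retained
        trials = cohort_with_missing({"A": {"ATD": 60, "BAL": 60, "ATL": 60}})
        kept, log = exclusion_filter(trials)
        assert set(kept["subject_id"]) == {"A"}
        assert log.empty

    def test_exactly_at_threshold_retained(self):
        # "more than 30%" is strict: 3/10 == 0.30 stays in
        trials = cohort_with_missing({"A": {"ATD": 3}}, n_trials=10)
        kept, _ = exclusion_filter(trials)
        assert not kept.empty

    def test_clean_subject_retained(self):
        trials = cohort_with_missing({"A": {"ATD": 0, "BAL": 0, "ATL": 0}})
        kept, log = exclusion_filter(trials)
        assert len(kept) == len(trials) and log.empty


class TestRMAnova:
    def test_constant_data_f_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            res = rm_anova_oneway(np.full((5, 3), 2.0))
        assert res.F == 0.0 and res.p == 1.0

    def test_identical_conditions_f_zero(self):
        data = np.tile(np.arange(5.0)[:, None], (1, 3))
        with pytest.warns(UserWarning, match="constant|zero error"):
            res = rm_anova_oneway(data)
        assert res.F == 0.0 and res.p == 1.0

    def test_zero_error_variance_sentinel(self):
        data = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        with pytest.warns(UserWarning, match="infinite-F"):
            res = rm_anova_oneway(data)
        assert np.isinf(res.F) and res.p == 0.0 and res.eta_p_sq == 1.0
        assert res.df_num == 1 and res.df_den == 2

    def test_matches_pingouin_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n, k = int(rng.integers(5, 30)), int(rng.integers(2, 5))
            data = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            long = pd.DataFrame(
                {
                    "s": np.repeat(np.arange(n), k),
                    "c": np.tile(np.arange(k), n),
                    "y": data.ravel(),
                }
            )
            oracle = pg.rm_anova(
                data=long, dv="y", within="c", subject="s", effsize="np2", correction=False
            ).iloc[0]
            res = rm_anova_oneway(data)
            assert res.F == pytest.approx(oracle["F"], abs=1e-8)
            assert res.p == pytest.approx(oracle["p_unc"], abs=1e-8)
            assert res.eta_p_sq == pytest.approx(oracle["np2"], abs=1e-8)
            assert (res.df_num, res.df_den) == (oracle["ddof1"], oracle["ddof2"])

    def test_type_one_error_calibration_quick(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            rm_anova_oneway(rng.normal(size=(20, 3))).p < 0.05 for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.09

    @pytest.mark.parametrize("shape", [(1, 3), (5, 1)])
    def test_minimum_size_enforced(self, shape):
        with pytest.raises(ValueError):
            rm_anova_oneway(np.zeros(shape))

    def test_incomplete_data_rejected(self):
        data = np.ones((4, 3))
        data[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            rm_anova_oneway(data)


class TestInterventionAnalysis:
    def test_report_shape_and_contents(self, small_cohort, small_cohort_fits):
        result = intervention_analysis(small_cohort.trials, small_cohort_fits)
        assert list(result.report["outcome"]) == [
            "mf_effect", "mb_effect",
            "beta1", "beta2", "alpha1", "alpha2", "lam", "omega", "pi",
        ]
        assert result.report["p"].between(0, 1).all()
        assert result.report["eta_p_sq"].between(0, 1).all()
        assert (result.report["df_num"] == 2).all()
        assert len(result.staytables) == 18

    def test_staytables_table_recomputes_effects(self, small_cohort):
        stay = cohort_staytables(small_cohort.trials)
        ok = stay.dropna(subset=["mf_effect"])
        recomputed = (
            ok["p_com_plus"] + ok["p_rar_plus"] - ok["p_com_minus"] - ok["p_rar_minus"]
        ) / 2
        np.testing.assert_allclose(ok["mf_effect"], recomputed, atol=1e-12)

    def test_single_subject_rejected(self, small_cohort, small_cohort_fits):
        one = small_cohort.trials[small_cohort.trials["subject_id"] == "S000"]
        fits = small_cohort_fits[small_cohort_fits["subject_id"] == "S000"]
        with pytest.raises(ValueError, match="fewer than 2"):
            intervention_analysis(one, fits)
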