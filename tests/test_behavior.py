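"""Mean splits, psychometric shift/slope fits, confidence analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from twentyone.behavior import (
    LogisticFit,
    condition_fits,
    confidence_accuracy_curves,
    decision_conf_bias_fit,
    fit_shift_slope,
    joint_confidence_matrix,
    mean_split,
    sessions_frame,
)


class TestMeanSplit:
    def test_basic_split(self):
        values = pd.Series([1, 1, 4, 4], dtype=float)
        by = pd.Series(["a"] * 4)
        assert list(mean_split(values, by)) == ["low", "low", "high", "high"]

    def test_constant_values_all_low(self):
        values = pd.Series([2.0, 2.0, 2.0])
        by = pd.Series(["a"] * 3)
        assert list(mean_split(values, by)) == ["low"] * 3

    def test_invariant_to_order(self):
        rng = np.random.default_rng(0)
        values = pd.Series(rng.integers(1, 5, 50).astype(float))
        by = pd.Series(["a"] * 50)
        labels = mean_split(values, by)
        perm = rng.permutation(50)
        labels_perm = mean_split(values.iloc[perm], by.iloc[perm])
        assert list(labels.iloc[perm]) == list(labels_perm)

    def test_per_participant_means(self):
        values = pd.Series([1.0, 3.0, 3.0, 5.0])
        by = pd.Series(["a", "a", "b", "b"])
        assert list(mean_split(values, by)) == ["low", "high", "low", "high"]


class TestFitShiftSlope:
    def test_recovers_generating_psychometric(self):
        rng = np.random.default_rng(5)
        faceup = rng.integers(8, 19, 5000)
        p = expit(-1.0 * (faceup - 13.0))
        hit = (rng.random(5000) < p).astype(float)
        fit = fit_shift_slope(faceup, hit)
        assert fit.converged
        assert fit.slope == pytest.approx(-1.0, abs=0.1)
        assert fit.shift == pytest.approx(13.0, abs=0.3)

    def test_all_hit_is_nonconverged(self):
        fit = fit_shift_slope([8, 10, 12, 14], [1, 1, 1, 1])
        assert not fit.converged

    def test_relabel_negates_slope_preserves_shift(self):
        rng = np.random.default_rng(6)
        faceup = rng.integers(8, 19, 4000)
        hit = (rng.random(4000) < expit(-0.8 * (faceup - 12.0))).astype(float)
        f1 = fit_shift_slope(faceup, hit)
        f2 = fit_shift_slope(faceup, 1 - hit)
        assert f1.slope == pytest.approx(-f2.slope, rel=1e-6)
        assert f1.shift == pytest.approx(f2.shift, rel=1e-6)

    def test_hierarchical_pools_participants(self):
        rng = np.random.default_rng(7)
        frames = []
        for pid, shift in zip("abc", (12.0, 13.0, 14.0)):
            faceup = rng.integers(8, 19, 2000)
            hit = (rng.random(2000) < expit(-1.0 * (faceup - shift))).astype(float)
            frames.append(pd.DataFrame({"p": pid, "faceup": faceup, "hit": hit}))
        df = pd.concat(frames)
        fit = fit_shift_slope(df["faceup"], df["hit"], df["p"], pooling="hierarchical")
        assert fit.converged
        assert fit.shift == pytest.approx(13.0, abs=0.3)
        assert len(fit.per_participant) == 3


class TestConditionFits:
    def test_cells_partition_trials(self, small_cohort):
        _, sessions = small_cohort
        table = condition_fits(sessions, split_variable="dec_conf")
        df = sessions_frame(sessions).dropna(subset=["deck_report", "dec_conf", "hit"])
        assert table["n_obs"].sum() == len(df)
        assert set(table["confidence"]) <= {"high", "low"}

    def test_shift_higher_under_deck4_reports(self, small_cohort):
        """Reporting Deck 4 lowers the expected additional score, so hitting
        stays attractive at higher face-up scores: larger shift."""
        _, sessions = small_cohort
        table = condition_fits(sessions, split_variable="dec_conf")
        ok = table[table["converged"]]
        by_deck = ok.groupby("deck_report")["shift"].mean()
        assert by_deck["4"] > by_deck["6"]

    def test_deck_conf_split_orders_shifts(self):
        """With strong confidence-weighted mixing (large gamma), high deck
        confidence pushes the score estimate toward the reported deck, so
        the psychometric shifts of the two deck reports separate further
        under high than under low deck confidence."""
        from scipy.special import logit

        from twentyone.synth import (
            CohortSpec,
            GroupParams,
            default_group_params,
            sample_cohort,
        )

        vals = dict(default_group_params().values)
        vals["gam_raw"] = (logit(0.45 / 0.5), 0.2)   # gamma ~ 0.45
        vals["eps_raw"] = (logit(0.45 / 0.5), 0.3)   # epsilon ~ 0.95
        _, sessions = sample_cohort(
            CohortSpec(n_participants=12, seed=11, group=GroupParams(vals))
        )
        table = condition_fits(sessions, split_variable="deck_conf")
        ok = table[table["converged"]]
        cell = ok.groupby(["deck_report", "confidence"])["shift"].mean()
        assert cell[("4", "high")] > cell[("4", "low")]
        assert cell[("6", "high")] < cell[("6", "low")]
        sep_high = cell[("4", "high")] - cell[("6", "high")]
        sep_low = cell[("4", "low")] - cell[("6", "low")]
        assert sep_high > sep_low


class TestConfidenceAccuracy:
    def test_perfect_reports_give_accuracy_one(self, small_cohort):
        _, sessions = small_cohort
        # overwrite reports with the true deck on a copy via the frame
        import copy

        forced = copy.deepcopy(sessions[:1])
        for config, rec in forced[0].iter_trials():
            rec.deck_report = config.additional_deck
        acc = confidence_accuracy_curves(forced)
        assert np.allclose(acc["deck_accuracy"]["rate"], 1.0)

    def test_positive_confidence_accuracy_correlation(self, small_cohort):
        _, sessions = small_cohort
        acc = confidence_accuracy_curves(sessions)
        assert acc["chance_level"] == 0.5
        assert acc["deck_group_r"] > 0
        assert acc["deck_individual_r"] > 0


class TestJointConfidenceMatrix:
    def test_diagonal_case(self, tiny_sessions):
        import copy

        forced = copy.deepcopy(tiny_sessions[:1])
        for i, (_, rec) in enumerate(forced[0].iter_trials()):
            rec.deck_conf_report = (i % 4) + 1
            rec.dec_conf_report = (i % 4) + 1
        out = joint_confidence_matrix(forced)
        assert np.allclose(np.diag(out["matrix"]), 0.25)
        assert out["disagreement"] == 0.0

    def test_matrix_normalized(self, small_cohort):
        _, sessions = small_cohort
        out = joint_confidence_matrix(sessions)
        assert out["matrix"].sum() == pytest.approx(1.0, abs=1e-12)
        assert 0 <= out["disagreement"] <= 1

    def test_independent_reports_uncorrelated(self):
        """Confidence reports drawn independently of each other yield a
        near-zero joint correlation (null simulation through the module)."""
        from twentyone.task import (
            DeckType,
            FaceDownDeckType,
            GameConfig,
            SessionData,
            TrialRecord,
        )

        rng = np.random.default_rng(12)
        cfg = GameConfig(DeckType.DECK4, FaceDownDeckType.L)
        records = [
            TrialRecord(
                game_index=0, trial_index=0, faceup=12, facedown=4, additional=4,
                deck_report=DeckType.DECK4,
                deck_conf_report=int(rng.integers(1, 5)),
                action="stay",
                dec_conf_report=int(rng.integers(1, 5)),
                payoff=16,
            )
            for _ in range(10_000)
        ]
        sess = SessionData("null", "behavioral", [(cfg, records)])
        out = joint_confidence_matrix([sess])
        assert abs(out["correlation"]) < 0.05
        assert out["n_trials"] == 10_000


class TestDecisionConfBias:
    def test_recovers_v_shape(self):
        """Synthetic V-shaped confidence with known vertex, bias, slope."""
        from twentyone.task import (
            DeckType,
            FaceDownDeckType,
            GameConfig,
            SessionData,
            TrialRecord,
        )

        rng = np.random.default_rng(9)
        games = []
        cfg = GameConfig(DeckType.DECK4, FaceDownDeckType.L)
        records = []
        for t in range(2000):
            faceup = int(rng.integers(8, 19))
            conf = 2.0 + 0.3 * abs(faceup - 13) + rng.normal(0, 0.2)
            conf_report = int(np.clip(round(conf), 1, 4))
            records.append(
                TrialRecord(
                    game_index=0, trial_index=0, faceup=faceup, facedown=4,
                    additional=4, deck_report=DeckType.DECK4, deck_conf_report=2,
                    action="stay", dec_conf_report=conf_report,
                    payoff=faceup + 4 if faceup + 4 <= 21 else 0,
                )
            )
        sess = SessionData("v", "behavioral", [(cfg, records)])
        out = decision_conf_bias_fit([sess])
        fits = out["fits"]
        assert (fits["vertex"] == 13).all()
        pooled_slope = np.average(fits["slope"], weights=fits["n_obs"])
        assert pooled_slope > 0.1  # rising flanks recovered

    def test_constant_confidence_gives_zero_slope(self, tiny_sessions):
        import copy

        forced = copy.deepcopy(tiny_sessions[:1])
        for _, rec in forced[0].iter_trials():
            rec.dec_conf_report = 3
        out = decision_conf_bias_fit(forced)
        assert np.allclose(out["fits"]["slope"], 0.0, atol=1e-12)

    def test_bias_increases_with_deck_confidence(self, small_cohort):
        """Positive c_k weight in the decision-confidence read-out shows up
        as bias rising with reported deck confidence."""
        _, sessions = small_cohort
        out = decision_conf_bias_fit(sessions)
        assert out["bias_conf_correlation"] > 0
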