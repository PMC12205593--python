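"""Evidence updating, confidence read-outs, discretization and likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from twentyone.dcmd import (
    DCMDParams,
    EvidenceState,
    confidence_report_pmf,
    deck6_probability,
    deck_confidence,
    decision_confidence,
    estimate_additional,
    hit_probability,
    prepare_session,
    session_loglik,
    simulate_agent_policy,
    update_evidence,
    value_belief,
)
from twentyone.task import (
    DeckType,
    FaceDownDeckType,
    GameConfig,
    SessionData,
    build_schedule,
    play_game,
)


class TestUpdateEvidence:
    def test_score_five_is_neutral(self):
        state = EvidenceState(1.0, 2.0)
        new = update_evidence(state, 5)
        assert (new.e_d4, new.e_d6) == (1.0, 2.0)

    def test_low_score_updates_deck4_only(self):
        new = update_evidence(EvidenceState(), 3)
        # normalized Deck-4 likelihood of a 3: p4(3)/(p4(3)+p6(3)),
        # exactly 0.6^4/(0.6^4 + 0.4^4) = 0.1296/0.1552
        assert new.e_d4 == pytest.approx(0.1296 / 0.1552, abs=1e-9)
        assert new.e_d6 == 0.0

    @given(st.lists(st.integers(0, 10), max_size=40))
    @settings(deadline=None)
    def test_incremental_equals_batch_and_monotone(self, scores):
        state = EvidenceState()
        prev = (0.0, 0.0)
        for s in scores:
            state = update_evidence(state, s)
            assert state.e_d4 >= prev[0] and state.e_d6 >= prev[1]
            # at most one side moved
            assert (state.e_d4 == prev[0]) or (state.e_d6 == prev[1])
            prev = (state.e_d4, state.e_d6)
        batch = EvidenceState()
        for s in scores:
            batch = update_evidence(batch, s)
        assert (batch.e_d4, batch.e_d6) == prev
        assert state.delta_e == state.e_d6 - state.e_d4

    def test_out_of_support_rejected(self):
        with pytest.raises(ValueError):
            update_evidence(EvidenceState(), 11)


class TestReadouts:
    def test_deck6_probability_values(self):
        assert deck6_probability(0.0, [0.0, 3.0]) == pytest.approx(0.5)
        assert deck6_probability(1.0, [0.0, 1.0]) == pytest.approx(0.731059, abs=1e-6)
        assert deck6_probability(100.0, [0.0, 1.0]) > 0.999

    def test_kappa_counts_current_report(self):
        state = EvidenceState()
        state.record_report(DeckType.DECK4)
        assert state.kappa == 1.0
        state.record_report(DeckType.DECK6)
        assert state.kappa == 0.5
        state = EvidenceState()
        for _ in range(3):
            state.record_report(DeckType.DECK6)
        assert state.kappa == 1.0

    def test_deck_confidence_at_zero_evidence(self):
        state = EvidenceState()
        state.record_report(DeckType.DECK4)
        assert deck_confidence(state, [0.0, 2.0, 0.0]) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "deck, eps, gam, ck, omega, a_hat",
        [
            (DeckType.DECK6, 0.9, 0.2, 0.5, 0.8, 5.6),
            (DeckType.DECK4, 0.75, 0.5, 0.5, 0.5, 5.0),
        ],
    )
    def test_estimate_additional(self, deck, eps, gam, ck, omega, a_hat):
        om, ah = estimate_additional(deck, ck, eps, gam)
        assert om == pytest.approx(omega)
        assert ah == pytest.approx(a_hat)

    def test_omega_equals_epsilon_at_full_confidence(self):
        om, _ = estimate_additional(DeckType.DECK4, 1.0 - 1e-12, 0.8, 0.3)
        assert om == pytest.approx(0.8)

    @given(
        ck=st.floats(0.01, 0.99),
        eps=st.floats(0.51, 0.99),
        gam=st.floats(0.0, 0.5),
        deck=st.sampled_from(list(DeckType)),
    )
    @settings(deadline=None)
    def test_a_hat_bounded(self, ck, eps, gam, deck):
        _, a_hat = estimate_additional(deck, ck, eps, gam)
        assert 4.0 <= a_hat <= 6.0

    def test_a_hat_limit_tracks_reported_deck(self):
        _, a_hat = estimate_additional(DeckType.DECK6, 1.0 - 1e-9, 0.999, 0.1)
        assert a_hat == pytest.approx(6.0, abs=5e-3)

    def test_parameter_bounds_enforced(self):
        with pytest.raises(ValueError):
            estimate_additional(DeckType.DECK4, 0.5, 0.4, 0.1)  # epsilon too small
        with pytest.raises(ValueError):
            estimate_additional(DeckType.DECK4, 0.5, 0.9, 0.95)  # gamma > epsilon

    @pytest.mark.parametrize(
        "faceup, p_low, a_hat, expected",
        [(13, 0.2, 4.0, 0.6), (18, 0.5, 6.0, -5.5)],
    )
    def test_value_belief(self, faceup, p_low, a_hat, expected):
        assert value_belief(faceup, p_low, a_hat) == pytest.approx(expected)

    def test_value_belief_linear_in_faceup(self):
        v1 = value_belief(10, 0.2, 5.0)
        v2 = value_belief(11, 0.2, 5.0)
        assert v1 - v2 == pytest.approx(1.0)

    def test_hit_probability(self):
        p, ds = hit_probability(0.0, [0.0, 1.0, 0.5])
        assert (p, ds) == (pytest.approx(0.5), 0.0)
        p, ds = hit_probability(2.0, [0.0, 1.0, 0.5])
        assert p == pytest.approx(0.98201, abs=1e-5)
        assert ds == pytest.approx(4.0)

    def test_hit_probability_monotone_in_value(self):
        v = np.linspace(-6, 6, 41)
        p = [hit_probability(x, [0.0, 0.7, 0.3])[0] for x in v]
        assert np.all(np.diff(p) > 0)

    def test_decision_confidence(self):
        assert decision_confidence(3.0, 0.5, [0.0, 0.0, 0.0]) == pytest.approx(0.5)
        assert decision_confidence(1.0, 0.5, [-1.0, 1.0, 2.0]) == pytest.approx(
            0.731059, abs=1e-6
        )

    def test_decision_confidence_increases_with_deck_confidence(self):
        cis = [decision_confidence(2.0, ck, [-1.0, 0.5, 2.0]) for ck in (0.1, 0.5, 0.9)]
        assert cis[0] < cis[1] < cis[2]


class TestConfidenceReportPmf:
    def test_symmetric_case(self):
        pmf = confidence_report_pmf(0.5, 1.0, [0.2, 0.5, 0.8])
        assert pmf == pytest.approx([0.38209, 0.11791, 0.11791, 0.38209], abs=1e-5)

    @given(
        c=st.floats(0.01, 0.99),
        sigma=st.floats(0.02, 3.0),
        lo=st.floats(0.05, 0.45),
        hi=st.floats(0.55, 0.95),
    )
    @settings(deadline=None)
    def test_valid_distribution(self, c, sigma, lo, hi):
        pmf = confidence_report_pmf(c, sigma, [lo, 0.5, hi])
        assert np.all(pmf >= 0)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_top_report_monotone_in_confidence(self):
        tops = [
            confidence_report_pmf(c, 0.3, [0.3, 0.5, 0.7])[3]
            for c in np.linspace(0.05, 0.95, 10)
        ]
        assert np.all(np.diff(tops) > 0)

    def test_bad_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            confidence_report_pmf(0.5, 1.0, [0.8, 0.5, 0.2])


def _simulate_session(params, n_games=5, seed=0, protocol="behavioral"):
    rng = np.random.default_rng(seed)
    agent = simulate_agent_policy(params, rng)
    games = []
    for g, cfg in enumerate(build_schedule(protocol, seed)[:n_games]):
        games.append((cfg, play_game(cfg, agent, rng, game_index=g)))
    return SessionData(participant_id="p0", protocol=protocol, games=games)


class TestSessionLoglik:
    def test_pointwise_sums_to_total(self, moderate_params):
        sess = _simulate_session(moderate_params, seed=3)
        total, pointwise = session_loglik(moderate_params, sess)
        assert total == pytest.approx(pointwise.sum(), abs=1e-9)
        assert len(pointwise) == sess.n_trials

    def test_first_trial_deck_term_is_log_half(self, moderate_params):
        # at dE = 0 the deck-report probability is sigmoid(intercept) = 0.5
        sess = _simulate_session(moderate_params, n_games=1, seed=4)
        p = moderate_params
        zero_int = DCMDParams(
            beta_k=[0.0, 5.0], beta_ck=p.beta_ck, epsilon=p.epsilon, gamma=p.gamma,
            beta_i=p.beta_i, beta_ci=p.beta_ci, sigma_k=p.sigma_k, sigma_i=p.sigma_i,
            theta_k=p.theta_k, theta_i=p.theta_i,
        )
        prep = prepare_session(sess)
        from twentyone.models import MODELS, dcmd_to_raw

        # isolate the deck term by masking the others
        prep.deck_conf_mask[:] = False
        prep.act_mask[:] = False
        prep.dec_conf_mask[:] = False
        pw = MODELS["dcmd"].pointwise_loglik(dcmd_to_raw(zero_int), prep)
        assert pw[0] == pytest.approx(np.log(0.5))

    def test_generating_params_beat_perturbed(self, moderate_params):
        # likelihood self-consistency over seeded sessions
        p = moderate_params
        worse = DCMDParams(
            beta_k=[2.0, -1.5], beta_ck=[1.0, -0.4, -1.5], epsilon=0.6, gamma=0.45,
            beta_i=[-1.0, -0.9, 0.0], beta_ci=[1.5, -0.5, -1.5],
            sigma_k=1.0, sigma_i=1.0, theta_k=[0.1, 0.5, 0.9], theta_i=[0.1, 0.5, 0.9],
        )
        diffs = []
        for seed in range(20):
            sess = _simulate_session(p, n_games=3, seed=seed)
            diffs.append(session_loglik(p, sess)[0] - session_loglik(worse, sess)[0])
        assert np.mean(diffs) > 0

    def test_kernel_matches_reference_implementation(self, small_cohort):
        # JIT kernel vs the readable numpy path, on simulated data
        from twentyone.dcmd import _pointwise_loglik
        from twentyone.models import MODELS, dcmd_from_raw

        rng = np.random.default_rng(0)
        _, sessions = small_cohort
        prep = prepare_session(sessions[0])
        for _ in range(5):
            raw = rng.normal(0, 1, 19)
            fast = MODELS["dcmd"].pointwise_loglik(raw, prep)
            slow = _pointwise_loglik(prep, dcmd_from_raw(raw))
            np.testing.assert_allclose(fast, slow, rtol=1e-10, atol=1e-10)


class TestAgent:
    def test_near_deterministic_agent_hits_on_positive_value(self, sharp_params):
        rng = np.random.default_rng(8)
        agent = simulate_agent_policy(sharp_params, rng)
        n_checked = n_consistent = 0
        for cfg in build_schedule("behavioral", 1)[:10]:
            agent.begin_game(cfg.facedown_deck)
            recs = play_game(cfg, agent, rng)
            for rec in recs:
                # with epsilon ~ 1, gamma 0: A_hat is the reported deck's mean
                a_hat = rec.deck_report.expected_score
                v = value_belief(rec.faceup, cfg.facedown_deck.p_low, a_hat)
                if abs(v) > 0.1:
                    n_checked += 1
                    n_consistent += (rec.action == "hit") == (v > 0)
        assert n_checked > 50
        assert n_consistent / n_checked >= 0.99

    def test_report_accuracy_rises_within_games(self, moderate_params):
        # evidence accumulation: late-trial reports beat early-trial reports
        rng = np.random.default_rng(21)
        agent = simulate_agent_policy(moderate_params, rng)
        correct = np.zeros(16)
        counts = np.zeros(16)
        for rep in range(200):
            cfg = build_schedule("behavioral", rep)[0]
            for rec in play_game(cfg, agent, rng):
                counts[rec.trial_index] += 1
                correct[rec.trial_index] += rec.deck_report is cfg.additional_deck
        acc = correct / counts
        rho = stats.spearmanr(np.arange(16), acc).statistic
        assert rho > 0
        assert acc[12:].mean() > acc[:4].mean()

    def test_all_report_pmfs_valid_on_simulated_trials(self, moderate_params):
        sess = _simulate_session(moderate_params, n_games=4, seed=9)
        prep = prepare_session(sess)
        from twentyone.inference import _model_pmfs
        from twentyone.models import MODELS, dcmd_to_raw

        p6, kc, ph, ic = _model_pmfs(MODELS["dcmd"], dcmd_to_raw(moderate_params), prep)
        assert np.all((p6 > 0) & (p6 < 1)) and np.all((ph > 0) & (ph < 1))
        for pmf in (kc, ic):
            assert np.all(pmf >= 0)
            np.testing.assert_allclose(pmf.sum(axis=1), 1.0, atol=1e-9)
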