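"""The deck-confidence-modulated decision (DC-MD) generative model.

The model has two linked phases. In the *deck-inference* phase the agent
accumulates evidence for each hidden additional-card deck by adding the
normalized likelihood of the latest revealed card to the deck it favors
(cards below 5 feed Deck-4 evidence, above 5 feed Deck-6 evidence, a score
of exactly 5 feeds neither). The reported deck follows a logistic read-out
of the evidence difference dE, and graded deck confidence c_k follows a
logistic read-out of |dE| and the within-game consistency rate kappa of the
agent's own reports. In the *decision* phase the expected additional score
A_hat mixes the reported deck's expectation with the alternative deck's,
with mixing weight omega = epsilon - gamma (1 - c_k): low deck confidence
pulls the estimate toward the alternative deck. The value-belief
V_hit = 21 - (faceup + E[facedown] + A_hat) drives a logistic hit/stay
choice with utility u = beta_i . (1, V, V|V|); decision simplicity DS = |u|
and the deck confidence jointly drive graded decision confidence c_i. Both
graded confidences are discretized to 4-point reports through a noisy
threshold (ordinal probit) model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._math import log_bernoulli, ordinal_report_logpmf_at, ordinal_report_pmf, sigmoid
from .task import (
    BUST_THRESHOLD,
    DeckType,
    FaceDownDeckType,
    Policy,
    SessionData,
    TrialResponse,
    additional_pmf,
)

__all__ = [
    "EvidenceState",
    "DCMDParams",
    "TrialLatents",
    "update_evidence",
    "deck6_probability",
    "deck_confidence",
    "estimate_additional",
    "value_belief",
    "hit_probability",
    "decision_confidence",
    "confidence_report_pmf",
    "session_loglik",
    "simulate_agent_policy",
    "DCMDAgent",
    "PreparedSession",
    "prepare_session",
]

# normalized per-score likelihoods, precomputed once: l4[s] = P(s|D4)/(P(s|D4)+P(s|D6))
_PMF4 = additional_pmf(DeckType.DECK4)
_PMF6 = additional_pmf(DeckType.DECK6)
_NORM4 = _PMF4 / (_PMF4 + _PMF6)
_NORM6 = _PMF6 / (_PMF4 + _PMF6)


@dataclass
class EvidenceState:
    """Accumulated within-game deck evidence and deck-report history."""

    e_d4: float = 0.0
    e_d6: float = 0.0
    report_history: list[DeckType] = field(default_factory=list)

    @property
    def delta_e(self) -> float:
        """Evidence difference dE = E_D6 - E_D4."""
        return self.e_d6 - self.e_d4

    @property
    def kappa(self) -> float:
        """Consistency rate: fraction of reports matching the latest one."""
        if not self.report_history:
            return 1.0
        current = self.report_history[-1]
        return sum(r is current for r in self.report_history) / len(self.report_history)

    def record_report(self, report: DeckType) -> None:
        self.report_history.append(report)


def update_evidence(state: EvidenceState, revealed_additional: int) -> EvidenceState:
    """Add the revealed card's normalized likelihood to the favored deck.

    Scores 0-4 increment Deck-4 evidence, 6-10 increment Deck-6 evidence and
    a score of exactly 5 (equal likelihood under both decks) leaves the
    state unchanged. Returns a new state; the input is not mutated.
    """
    s = int(revealed_additional)
    if not 0 <= s <= 10:
        raise ValueError(f"additional-card score {s} outside support 0..10")
    e4, e6 = state.e_d4, state.e_d6
    if s < 5:
        e4 += float(_NORM4[s])
    elif s > 5:
        e6 += float(_NORM6[s])
    return EvidenceState(e4, e6, list(state.report_history))


def deck6_probability(delta_e: float, beta_k: Sequence[float]) -> float:
    """P(report = Deck 6) = sigmoid(beta_k . (1, dE))."""
    b = np.asarray(beta_k, dtype=float)
    return float(sigmoid(b[0] + b[1] * delta_e))


def deck_confidence(state: EvidenceState, beta_ck: Sequence[float]) -> float:
    """Graded deck confidence c_k = sigmoid(beta_ck . (1, |dE|, kappa)).

    ``state.kappa`` must already include the current trial's report.
    """
    b = np.asarray(beta_ck, dtype=float)
    return float(sigmoid(b[0] + b[1] * abs(state.delta_e) + b[2] * state.kappa))


def estimate_additional(
    reported_deck: DeckType, c_k: float, epsilon: float, gamma: float
) -> tuple[float, float]:
    """Confidence-weighted additional-score estimate.

    omega = epsilon - gamma (1 - c_k), clamped to [0, 1];
    A_hat = omega E_d(A) + (1 - omega) E_dbar(A) with E_Deck4 = 4, E_Deck6 = 6.
    """
    if not 0.0 <= c_k <= 1.0:  # closed: the logistic saturates in floats
        raise ValueError("c_k must lie in [0, 1]")
    if not 0.5 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0.5, 1)")
    if not 0.0 <= gamma <= epsilon:
        raise ValueError("gamma must lie in [0, epsilon]")
    omega = float(np.clip(epsilon - gamma * (1.0 - c_k), 0.0, 1.0))
    a_hat = omega * reported_deck.expected_score + (1.0 - omega) * reported_deck.other.expected_score
    return omega, a_hat


def value_belief(faceup: int, p_low: float, a_hat: float) -> float:
    """Margin to the bust threshold expected from hitting:
    V_hit = 21 - (faceup + E[facedown] + A_hat)."""
    fd_exp = p_low * 1.0 + (1.0 - p_low) * 4.0
    return BUST_THRESHOLD - (faceup + fd_exp + a_hat)


def hit_probability(v_hit: float, beta_i: Sequence[float]) -> tuple[float, float]:
    """(P(hit), decision simplicity DS) from utility
    u = beta_i . (1, V, V|V|); DS = |u|."""
    b = np.asarray(beta_i, dtype=float)
    u = b[0] + b[1] * v_hit + b[2] * v_hit * abs(v_hit)
    return float(sigmoid(u)), float(abs(u))


def decision_confidence(ds: float, c_k: float, beta_ci: Sequence[float]) -> float:
    """Graded decision confidence c_i = sigmoid(beta_ci . (1, DS, c_k))."""
    b = np.asarray(beta_ci, dtype=float)
    return float(sigmoid(b[0] + b[1] * ds + b[2] * c_k))


def confidence_report_pmf(c: float, sigma: float, theta: Sequence[float]) -> np.ndarray:
    """pmf of the 4-point report of a graded confidence (ordinal probit)."""
    return ordinal_report_pmf(c, sigma, theta)


@dataclass
class DCMDParams:
    """One agent's full DC-MD parameter vector.

    Deck-inference side (8 free scalars): ``beta_k`` (intercept, dE weight),
    ``beta_ck`` (intercept, |dE| weight, kappa weight), report noise
    ``sigma_k`` and thresholds ``theta_k`` (middle threshold fixed at 0.5).
    Decision side (11): ``beta_i``, ``beta_ci``, the mixing bounds
    ``epsilon`` in (0.5, 1) and ``gamma`` in [0, epsilon], ``sigma_i``,
    ``theta_i``.
    """

    beta_k: np.ndarray
    beta_ck: np.ndarray
    epsilon: float
    gamma: float
    beta_i: np.ndarray
    beta_ci: np.ndarray
    sigma_k: float
    sigma_i: float
    theta_k: np.ndarray
    theta_i: np.ndarray

    def __post_init__(self) -> None:
        self.beta_k = np.asarray(self.beta_k, dtype=float)
        self.beta_ck = np.asarray(self.beta_ck, dtype=float)
        self.beta_i = np.asarray(self.beta_i, dtype=float)
        self.beta_ci = np.asarray(self.beta_ci, dtype=float)
        self.theta_k = np.asarray(self.theta_k, dtype=float)
        self.theta_i = np.asarray(self.theta_i, dtype=float)
        if self.beta_k.shape != (2,):
            raise ValueError("beta_k must have 2 entries")
        for name, vec in (("beta_ck", self.beta_ck), ("beta_i", self.beta_i), ("beta_ci", self.beta_ci)):
            if vec.shape != (3,):
                raise ValueError(f"{name} must have 3 entries")
        if not 0.5 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0.5, 1)")
        if not 0.0 <= self.gamma <= self.epsilon:
            raise ValueError("gamma must lie in [0, epsilon]")
        if self.sigma_k <= 0 or self.sigma_i <= 0:
            raise ValueError("report noise sigma must be positive")
        for name, th in (("theta_k", self.theta_k), ("theta_i", self.theta_i)):
            if th.shape != (3,):
                raise ValueError(f"{name} must be a threshold triple")
            if not (th[0] < th[1] < th[2]):
                raise ValueError(f"{name} must be strictly increasing")


@dataclass
class TrialLatents:
    """Per-trial model quantities, for inspection and plotting."""

    p_deck6: float
    c_k: float
    omega: float
    a_hat: float
    v_hit: float
    p_hit: float
    ds: float
    c_i: float
    deck_conf_pmf: np.ndarray
    dec_conf_pmf: np.ndarray


# ---------------------------------------------------------------------------
# Vectorized session preparation and likelihood
# ---------------------------------------------------------------------------

@dataclass
class PreparedSession:
    """Design arrays for one participant's session, precomputed once.

    When fitting, the *observed* deck reports drive kappa and the
    reported-deck expectations, and the evidence trajectory depends only on
    the card sequence — so everything the likelihood needs besides the
    parameters is fixed and the likelihood is a pure vectorized function.
    Missing deck reports carry the previous report forward; before any
    report exists the sign of dE (Deck 4 at dE <= 0) stands in.
    """

    delta_e: np.ndarray
    abs_delta_e: np.ndarray
    kappa: np.ndarray
    e_rep: np.ndarray  # expected additional score of the reported deck
    e_alt: np.ndarray
    faceup: np.ndarray
    fd_exp: np.ndarray
    deck_is6: np.ndarray
    deck_mask: np.ndarray
    hit: np.ndarray
    act_mask: np.ndarray
    deck_conf: np.ndarray
    deck_conf_mask: np.ndarray
    dec_conf: np.ndarray
    dec_conf_mask: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.faceup.shape[0]


def prepare_session(session: SessionData) -> PreparedSession:
    cols: dict[str, list] = {k: [] for k in (
        "delta_e", "kappa", "e_rep", "faceup", "fd_exp",
        "deck_is6", "deck_mask", "hit", "act_mask",
        "deck_conf", "deck_conf_mask", "dec_conf", "dec_conf_mask",
    )}
    for config, trials in session.games:
        state = EvidenceState()
        effective: list[DeckType] = []
        for rec in trials:
            cols["delta_e"].append(state.delta_e)
            report = rec.deck_report
            if report is None:
                if effective:
                    report = effective[-1]
                else:
                    report = DeckType.DECK6 if state.delta_e > 0 else DeckType.DECK4
            effective.append(report)
            kappa = sum(r is report for r in effective) / len(effective)
            cols["kappa"].append(kappa)
            cols["e_rep"].append(report.expected_score)
            cols["faceup"].append(rec.faceup)
            cols["fd_exp"].append(config.facedown_deck.expected_score)
            cols["deck_is6"].append(1 if rec.deck_report is DeckType.DECK6 else 0)
            cols["deck_mask"].append(rec.deck_report is not None)
            cols["hit"].append(1 if rec.action == "hit" else 0)
            cols["act_mask"].append(rec.action is not None)
            cols["deck_conf"].append(rec.deck_conf_report or 1)
            cols["deck_conf_mask"].append(rec.deck_conf_report is not None)
            cols["dec_conf"].append(rec.dec_conf_report or 1)
            cols["dec_conf_mask"].append(rec.dec_conf_report is not None)
            state = update_evidence(state, rec.additional)
    f = lambda k, dt: np.asarray(cols[k], dtype=dt)
    delta_e = f("delta_e", float)
    e_rep = f("e_rep", float)
    return PreparedSession(
        delta_e=delta_e,
        abs_delta_e=np.abs(delta_e),
        kappa=f("kappa", float),
        e_rep=e_rep,
        e_alt=10.0 - e_rep,  # E_Deck4 + E_Deck6 = 10
        faceup=f("faceup", float),
        fd_exp=f("fd_exp", float),
        deck_is6=f("deck_is6", int),
        deck_mask=f("deck_mask", bool),
        hit=f("hit", int),
        act_mask=f("act_mask", bool),
        deck_conf=f("deck_conf", int),
        deck_conf_mask=f("deck_conf_mask", bool),
        dec_conf=f("dec_conf", int),
        dec_conf_mask=f("dec_conf_mask", bool),
    )


def _pointwise_loglik(prep: PreparedSession, p: DCMDParams) -> np.ndarray:
    """Per-trial log-likelihood: the sum of the (available) deck-report,
    deck-confidence, action and decision-confidence terms."""
    logit_p6 = p.beta_k[0] + p.beta_k[1] * prep.delta_e
    ll = np.where(prep.deck_mask, log_bernoulli(prep.deck_is6, logit_p6), 0.0)

    c_k = sigmoid(p.beta_ck[0] + p.beta_ck[1] * prep.abs_delta_e + p.beta_ck[2] * prep.kappa)
    ll_kc = ordinal_report_logpmf_at(c_k, p.sigma_k, p.theta_k, prep.deck_conf)
    ll = ll + np.where(prep.deck_conf_mask, ll_kc, 0.0)

    omega = np.clip(p.epsilon - p.gamma * (1.0 - c_k), 0.0, 1.0)
    a_hat = omega * prep.e_rep + (1.0 - omega) * prep.e_alt
    v = BUST_THRESHOLD - (prep.faceup + prep.fd_exp + a_hat)
    u = p.beta_i[0] + p.beta_i[1] * v + p.beta_i[2] * v * np.abs(v)
    ll = ll + np.where(prep.act_mask, log_bernoulli(prep.hit, u), 0.0)

    c_i = sigmoid(p.beta_ci[0] + p.beta_ci[1] * np.abs(u) + p.beta_ci[2] * c_k)
    ll_ic = ordinal_report_logpmf_at(c_i, p.sigma_i, p.theta_i, prep.dec_conf)
    ll = ll + np.where(prep.dec_conf_mask, ll_ic, 0.0)
    return ll


def session_loglik(
    params: DCMDParams, session: SessionData | PreparedSession
) -> tuple[float, np.ndarray]:
    """Total and per-trial DC-MD log-likelihood of one observed session.

    Evidence resets at each game boundary; missing reports drop only their
    own term. Raises if the result is nonfinite (with the offending trial).
    """
    prep = session if isinstance(session, PreparedSession) else prepare_session(session)
    pointwise = _pointwise_loglik(prep, params)
    if not np.all(np.isfinite(pointwise)):
        bad = int(np.flatnonzero(~np.isfinite(pointwise))[0])
        raise FloatingPointError(f"nonfinite log-likelihood at trial {bad}")
    return float(pointwise.sum()), pointwise


# ---------------------------------------------------------------------------
# Generative agent
# ---------------------------------------------------------------------------

class DCMDAgent:
    """Policy that samples all four reports from the DC-MD likelihoods."""

    def __init__(self, params: DCMDParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self._state = EvidenceState()
        self._p_low = 0.5

    def begin_game(self, facedown_deck: FaceDownDeckType) -> None:
        self._state = EvidenceState()
        self._p_low = facedown_deck.p_low

    def decide(
        self, trial_index: int, faceup: int, prev_additional: int | None
    ) -> TrialResponse:
        p = self.params
        if prev_additional is not None:
            self._state = update_evidence(self._state, prev_additional)
        p6 = deck6_probability(self._state.delta_e, p.beta_k)
        report = DeckType.DECK6 if self.rng.random() < p6 else DeckType.DECK4
        self._state.record_report(report)
        c_k = deck_confidence(self._state, p.beta_ck)
        deck_conf = 1 + int(
            self.rng.choice(4, p=confidence_report_pmf(c_k, p.sigma_k, p.theta_k))
        )
        _, a_hat = estimate_additional(report, c_k, p.epsilon, p.gamma)
        v = value_belief(faceup, self._p_low, a_hat)
        p_hit, ds = hit_probability(v, p.beta_i)
        action = "hit" if self.rng.random() < p_hit else "stay"
        c_i = decision_confidence(ds, c_k, p.beta_ci)
        dec_conf = 1 + int(
            self.rng.choice(4, p=confidence_report_pmf(c_i, p.sigma_i, p.theta_i))
        )
        return TrialResponse(report, deck_conf, action, dec_conf)


def simulate_agent_policy(params: DCMDParams, rng: np.random.Generator) -> DCMDAgent:
    """Agent callback for :func:`twentyone.task.play_game` that samples the
    deck report, both 4-point confidence reports and the hit/stay action
    from the DC-MD model at ``params``."""
    return DCMDAgent(params, rng)
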