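"""Alternative behavioral models for comparison with DC-MD.

* DC-ID — deck-confidence-*independent* decision model: identical deck
  inference, but the additional-score estimate uses the reported deck's
  expectation directly (no confidence-weighted mixing) and decision
  confidence has no deck-confidence term. DC-ID is exactly nested in DC-MD
  (epsilon -> 1, gamma -> 0, zero c_k weight in beta_ci).
* HGF — a three-level hierarchical Gaussian filter over the deck tendency
  and its volatility, driven by the normalized Deck-6 likelihood of each
  revealed card; deck confidence reads out the predicted volatility.
* Averaging — deck inference from the running mean of revealed card scores
  minus the midpoint 5.
* Optimal Bayes — exact posterior over the two decks, with deck confidence
  read out from the posterior entropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._math import log_bernoulli, ordinal_report_logpmf_at, sigmoid
from .dcmd import (
    DCMDParams,
    PreparedSession,
    _PMF4,
    _PMF6,
    decision_confidence,
    hit_probability,
    value_belief,
)
from .task import BUST_THRESHOLD, DeckType

__all__ = [
    "DCIDParams",
    "dcid_trial",
    "dcid_pointwise_loglik",
    "HGFParams",
    "HGFState",
    "hgf_input",
    "hgf_step",
    "hgf_outputs",
    "BayesState",
    "averaging_inference",
    "bayes_inference",
    "hgf_session_loglik",
    "averaging_session_loglik",
    "bayes_session_loglik",
]


# ---------------------------------------------------------------------------
# DC-ID
# ---------------------------------------------------------------------------

@dataclass
class DCIDParams:
    """DC-ID parameter vector: as DC-MD but beta_ci has no c_k term and
    there is no (epsilon, gamma) mixing."""

    beta_k: np.ndarray
    beta_ck: np.ndarray
    beta_i: np.ndarray
    beta_ci: np.ndarray  # (intercept, DS weight)
    sigma_k: float
    sigma_i: float
    theta_k: np.ndarray
    theta_i: np.ndarray

    def __post_init__(self) -> None:
        for name in ("beta_k", "beta_ck", "beta_i", "beta_ci", "theta_k", "theta_i"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.beta_ci.shape != (2,):
            raise ValueError("DC-ID beta_ci must have 2 entries (intercept, DS)")
        if self.sigma_k <= 0 or self.sigma_i <= 0:
            raise ValueError("report noise sigma must be positive")


def dcid_trial(
    params, faceup: int, p_low: float, reported_deck: DeckType
) -> tuple[float, float, float, float]:
    """One DC-ID decision-phase trial: (V_hit, p_hit, DS, c_i).

    The additional-score estimate is the reported deck's expectation; c_i
    depends on DS only.
    """
    v = value_belief(faceup, p_low, reported_deck.expected_score)
    p_hit, ds = hit_probability(v, params.beta_i)
    b = np.asarray(params.beta_ci, dtype=float)
    c_i = float(sigmoid(b[0] + b[1] * ds))
    return v, p_hit, ds, c_i


def dcid_pointwise_loglik(prep: PreparedSession, p: DCIDParams) -> np.ndarray:
    """Per-trial DC-ID log-likelihood on a prepared session (same design
    arrays as DC-MD; the deck-inference phase is shared)."""
    logit_p6 = p.beta_k[0] + p.beta_k[1] * prep.delta_e
    ll = np.where(prep.deck_mask, log_bernoulli(prep.deck_is6, logit_p6), 0.0)

    c_k = sigmoid(p.beta_ck[0] + p.beta_ck[1] * prep.abs_delta_e + p.beta_ck[2] * prep.kappa)
    ll_kc = ordinal_report_logpmf_at(c_k, p.sigma_k, p.theta_k, prep.deck_conf)
    ll = ll + np.where(prep.deck_conf_mask, ll_kc, 0.0)

    v = BUST_THRESHOLD - (prep.faceup + prep.fd_exp + prep.e_rep)
    u = p.beta_i[0] + p.beta_i[1] * v + p.beta_i[2] * v * np.abs(v)
    ll = ll + np.where(prep.act_mask, log_bernoulli(prep.hit, u), 0.0)

    c_i = sigmoid(p.beta_ci[0] + p.beta_ci[1] * np.abs(u))
    ll_ic = ordinal_report_logpmf_at(c_i, p.sigma_i, p.theta_i, prep.dec_conf)
    ll = ll + np.where(prep.dec_conf_mask, ll_ic, 0.0)
    return ll


# ---------------------------------------------------------------------------
# Three-level HGF
# ---------------------------------------------------------------------------

@dataclass
class HGFParams:
    """Three-level binary HGF parameters.

    ``hgf_kappa`` couples levels 2 and 3; ``omega2``/``omega3`` are the
    unweighted level-2/3 learning rates. ``omega3`` enters the level-3
    prediction variance *additively* (sigma3_hat = sigma3 + omega3), unlike
    the common exp(omega3) form, so it must effectively act as a positive
    diffusion variance: nonpositive prediction variances are rejected at
    run time. The default 0.1 keeps the level-3 variance stationary.
    """

    hgf_kappa: float = 1.0
    omega2: float = -2.0
    omega3: float = 0.1
    beta_ck_hgf: np.ndarray = None  # (intercept, mu3_hat weight)
    beta_i: np.ndarray = None
    beta_ci_hgf: np.ndarray = None  # (intercept, DS, mu3_hat)
    sigma_k: float = 0.2
    sigma_i: float = 0.2
    theta_k: np.ndarray = None
    theta_i: np.ndarray = None
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0

    def __post_init__(self) -> None:
        if self.hgf_kappa <= 0:
            raise ValueError("hgf_kappa must be positive")
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("initial variances must be positive")
        defaults = {
            "beta_ck_hgf": [0.0, -1.0],
            "beta_i": [0.0, 1.0, 0.2],
            "beta_ci_hgf": [0.0, 0.5, -1.0],
            "theta_k": [0.3, 0.5, 0.7],
            "theta_i": [0.3, 0.5, 0.7],
        }
        for name, default in defaults.items():
            val = getattr(self, name)
            setattr(self, name, np.asarray(default if val is None else val, dtype=float))


@dataclass
class HGFState:
    """Posteriors, predictions, prediction errors and weights of one step."""

    mu1: float = 0.5
    mu2: float = 0.0
    mu3: float = 1.0
    sigma2: float = 1.0
    sigma3: float = 1.0
    # predictions for the current trial (filled by hgf_step)
    mu1_hat: float = 0.5
    mu2_hat: float = 0.0
    mu3_hat: float = 1.0
    sigma1_hat: float = 0.25
    sigma2_hat: float = 1.0
    sigma3_hat: float = 1.0
    delta1: float = 0.0
    delta2: float = 0.0
    w2: float = 0.0
    r2: float = 0.0

    @property
    def pi2(self) -> float:
        return 1.0 / self.sigma2

    @property
    def pi3(self) -> float:
        return 1.0 / self.sigma3


def hgf_input(revealed_additional: int) -> float:
    """Normalized Deck-6 likelihood of a revealed card score."""
    s = int(revealed_additional)
    if not 0 <= s <= 10:
        raise ValueError(f"score {s} outside support 0..10")
    return float(_PMF6[s] / (_PMF4[s] + _PMF6[s]))


def hgf_step(state: HGFState, l: float, params: HGFParams) -> HGFState:
    """One HGF update from input ``l`` in (0, 1). Returns a new state whose
    ``*_hat`` fields are the predictions that generated this trial's
    read-outs. Raises on nonpositive precision ("HGF divergence")."""
    k, w2p, w3p = params.hgf_kappa, params.omega2, params.omega3
    # predictions
    mu2_hat = state.mu2
    mu3_hat = state.mu3
    mu1_hat = float(sigmoid(mu2_hat))
    sigma1_hat = mu1_hat * (1.0 - mu1_hat)
    vol = float(np.exp(k * state.mu3 + w2p))
    sigma2_hat = state.sigma2 + vol
    sigma3_hat = state.sigma3 + w3p
    if sigma2_hat <= 0 or sigma3_hat <= 0:
        raise FloatingPointError("HGF divergence: nonpositive prediction variance")
    # level 1-2
    mu1 = float(l)
    delta1 = mu1 - mu1_hat
    pi2 = 1.0 / sigma2_hat + sigma1_hat
    sigma2 = 1.0 / pi2
    mu2 = mu2_hat + sigma2 * delta1
    # level-2 PE and weights
    delta2 = (sigma2 + (mu2 - mu2_hat) ** 2) / (vol + state.sigma2) - 1.0
    w2 = vol / (vol + state.sigma2)
    r2 = 2.0 * w2 - 1.0
    # level 3
    pi3 = 1.0 / sigma3_hat + (k**2 / 2.0) * w2 * (w2 + r2 * delta2)
    if pi3 <= 0:
        raise FloatingPointError("HGF divergence: nonpositive level-3 precision")
    sigma3 = 1.0 / pi3
    mu3 = mu3_hat + (k / 2.0) * sigma3 * w2 * delta2
    return HGFState(
        mu1=mu1, mu2=mu2, mu3=mu3, sigma2=sigma2, sigma3=sigma3,
        mu1_hat=mu1_hat, mu2_hat=mu2_hat, mu3_hat=mu3_hat,
        sigma1_hat=sigma1_hat, sigma2_hat=sigma2_hat, sigma3_hat=sigma3_hat,
        delta1=delta1, delta2=delta2, w2=w2, r2=r2,
    )


def hgf_outputs(
    state: HGFState, params: HGFParams, faceup: int, p_low: float
) -> tuple[float, float, float, float, float, float]:
    """(p_deck6, c_k, A_hat, V_hit, p_hit, c_i) from the current predictions.

    The deck probability is the predicted level-1 mean; deck confidence
    reads out the predicted volatility mu3_hat; the additional-score
    estimate mixes the two deck expectations by mu1_hat.
    """
    p6 = state.mu1_hat
    b = params.beta_ck_hgf
    c_k = float(sigmoid(b[0] + b[1] * state.mu3_hat))
    a_hat = (1.0 - p6) * DeckType.DECK4.expected_score + p6 * DeckType.DECK6.expected_score
    v = value_belief(faceup, p_low, a_hat)
    p_hit, ds = hit_probability(v, params.beta_i)
    bc = params.beta_ci_hgf
    c_i = float(sigmoid(bc[0] + bc[1] * ds + bc[2] * state.mu3_hat))
    return p6, c_k, a_hat, v, p_hit, c_i


# ---------------------------------------------------------------------------
# Averaging and optimal-Bayes deck inference
# ---------------------------------------------------------------------------

def averaging_inference(card_history: Sequence[int], beta_k: Sequence[float]) -> float:
    """Deck-6 probability from the running mean of revealed scores:
    dE = mean(history) - 5 (0 for an empty history), through the logistic
    read-out."""
    hist = np.asarray(card_history, dtype=float)
    delta_e = float(hist.mean() - 5.0) if hist.size else 0.0
    b = np.asarray(beta_k, dtype=float)
    return float(sigmoid(b[0] + b[1] * delta_e))


@dataclass
class BayesState:
    """Exact posterior over the two additional-card decks, plus its entropy."""

    posterior: np.ndarray = None  # (P(Deck4), P(Deck6))

    def __post_init__(self) -> None:
        if self.posterior is None:
            self.posterior = np.array([0.5, 0.5])
        self.posterior = np.asarray(self.posterior, dtype=float)
        if self.posterior.shape != (2,) or not np.isclose(self.posterior.sum(), 1.0):
            raise ValueError("posterior must be a length-2 distribution")

    @property
    def entropy(self) -> float:
        """Shannon entropy Q in nats; ln 2 at the uniform posterior."""
        p = self.posterior[self.posterior > 0]
        return float(-(p * np.log(p)).sum())


def bayes_inference(prior: BayesState, revealed_additional: int) -> BayesState:
    """Exact Bayes update of the deck posterior by one revealed card."""
    s = int(revealed_additional)
    if not 0 <= s <= 10:
        raise ValueError(f"score {s} outside support 0..10")
    unnorm = prior.posterior * np.array([_PMF4[s], _PMF6[s]])
    z = unnorm.sum()
    if z <= 0:
        raise ZeroDivisionError("zero normalizer in Bayes update")
    return BayesState(unnorm / z)


# ---------------------------------------------------------------------------
# Point-parameter session likelihoods for the alternative models
# ---------------------------------------------------------------------------
# These evaluate one observed session at fixed parameters (CLI `loglik`,
# exploratory comparison). They loop trial by trial because their latent
# trajectories depend on the parameters; only DC-MD and DC-ID, whose design
# arrays are parameter-free, have vectorized kernels and hierarchical fits.

def _ordinal_logp_scalar(c: float, sigma: float, theta, report: int) -> float:
    from ._math import ordinal_report_pmf

    p = ordinal_report_pmf(c, sigma, theta)[report - 1]
    return float(np.log(max(p, 1e-300)))


def _decision_terms(params, c_k: float, a_hat: float, rec, p_low: float):
    """Action and decision-confidence log-likelihood terms shared by the
    DC-MD-style decision phase (value-belief, utility, ordinal report)."""
    from scipy.special import log_expit

    v = value_belief(rec.faceup, p_low, a_hat)
    b = params.beta_i
    u = b[0] + b[1] * v + b[2] * v * abs(v)
    ll = 0.0
    if rec.action is not None:
        ll += float(log_expit(u) if rec.action == "hit" else log_expit(-u))
    if rec.dec_conf_report is not None:
        bc = params.beta_ci
        if len(bc) == 3:
            c_i = float(sigmoid(bc[0] + bc[1] * abs(u) + bc[2] * c_k))
        else:
            c_i = float(sigmoid(bc[0] + bc[1] * abs(u)))
        ll += _ordinal_logp_scalar(c_i, params.sigma_i, params.theta_i, rec.dec_conf_report)
    return ll


def hgf_session_loglik(params: HGFParams, session) -> tuple[float, np.ndarray]:
    """Total and per-trial HGF log-likelihood of one observed session.

    The deck-report probability is the predicted level-1 mean, deck
    confidence reads out the predicted volatility, and the decision phase
    reuses the value-belief machinery with A_hat mixed by the deck belief.
    """
    from scipy.special import log_expit

    pointwise = []
    for config, trials in session.games:
        state = HGFState(
            mu2=params.mu2_0, sigma2=params.sigma2_0,
            mu3=params.mu3_0, sigma3=params.sigma3_0,
        )
        p_low = config.facedown_deck.p_low
        seeded = hgf_step(state, 0.5, params)  # predictions for trial 1
        current = state
        for t, rec in enumerate(trials):
            if t > 0:
                current = hgf_step(current, hgf_input(trials[t - 1].additional), params)
                pred = current
            else:
                pred = seeded
            p6, c_k, a_hat, _, _, _ = hgf_outputs(pred, params, rec.faceup, p_low)
            ll = 0.0
            if rec.deck_report is not None:
                p6c = min(max(p6, 1e-300), 1 - 1e-16)
                ll += float(np.log(p6c if rec.deck_report is DeckType.DECK6 else 1 - p6c))
            if rec.deck_conf_report is not None:
                ll += _ordinal_logp_scalar(
                    c_k, params.sigma_k, params.theta_k, rec.deck_conf_report
                )
            # decision phase: same utility form as DC-MD
            b = params.beta_i
            v = value_belief(rec.faceup, p_low, a_hat)
            u = b[0] + b[1] * v + b[2] * v * abs(v)
            if rec.action is not None:
                ll += float(log_expit(u) if rec.action == "hit" else log_expit(-u))
            if rec.dec_conf_report is not None:
                bc = params.beta_ci_hgf
                c_i = float(sigmoid(bc[0] + bc[1] * abs(u) + bc[2] * pred.mu3_hat))
                ll += _ordinal_logp_scalar(
                    c_i, params.sigma_i, params.theta_i, rec.dec_conf_report
                )
            pointwise.append(ll)
    pw = np.array(pointwise)
    if not np.all(np.isfinite(pw)):
        bad = int(np.flatnonzero(~np.isfinite(pw))[0])
        raise FloatingPointError(f"nonfinite log-likelihood at trial {bad}")
    return float(pw.sum()), pw


def averaging_session_loglik(params, session) -> tuple[float, np.ndarray]:
    """DC-MD likelihood with the evidence difference replaced by the
    running mean of revealed card scores minus 5 (``params``: DCMDParams)."""
    from scipy.special import log_expit

    from .dcmd import estimate_additional

    pointwise = []
    for config, trials in session.games:
        p_low = config.facedown_deck.p_low
        history: list[int] = []
        reports: list[DeckType] = []
        for rec in trials:
            delta_e = float(np.mean(history) - 5.0) if history else 0.0
            ll = 0.0
            p6 = averaging_inference(history, params.beta_k)
            if rec.deck_report is not None:
                p6c = min(max(p6, 1e-300), 1 - 1e-16)
                ll += float(np.log(p6c if rec.deck_report is DeckType.DECK6 else 1 - p6c))
            report = rec.deck_report
            if report is None:
                report = reports[-1] if reports else (
                    DeckType.DECK6 if delta_e > 0 else DeckType.DECK4
                )
            reports.append(report)
            kappa = sum(r is report for r in reports) / len(reports)
            bck = params.beta_ck
            c_k = float(sigmoid(bck[0] + bck[1] * abs(delta_e) + bck[2] * kappa))
            if rec.deck_conf_report is not None:
                ll += _ordinal_logp_scalar(
                    c_k, params.sigma_k, params.theta_k, rec.deck_conf_report
                )
            _, a_hat = estimate_additional(report, c_k, params.epsilon, params.gamma)
            ll += _decision_terms(params, c_k, a_hat, rec, p_low)
            pointwise.append(ll)
            history.append(rec.additional)
    pw = np.array(pointwise)
    return float(pw.sum()), pw


def bayes_session_loglik(params, session) -> tuple[float, np.ndarray]:
    """DC-MD likelihood with exact-Bayes deck inference: the deck-report
    probability is the posterior itself and deck confidence reads out the
    posterior entropy Q and consistency rate (``params``: DCMDParams,
    whose beta_ck |dE| weight multiplies Q)."""
    from .dcmd import estimate_additional

    pointwise = []
    for config, trials in session.games:
        p_low = config.facedown_deck.p_low
        state = BayesState()
        reports: list[DeckType] = []
        for rec in trials:
            ll = 0.0
            p6 = float(state.posterior[1])
            if rec.deck_report is not None:
                p6c = min(max(p6, 1e-300), 1 - 1e-16)
                ll += float(np.log(p6c if rec.deck_report is DeckType.DECK6 else 1 - p6c))
            report = rec.deck_report
            if report is None:
                report = reports[-1] if reports else (
                    DeckType.DECK6 if p6 > 0.5 else DeckType.DECK4
                )
            reports.append(report)
            kappa = sum(r is report for r in reports) / len(reports)
            bck = params.beta_ck
            c_k = float(sigmoid(bck[0] + bck[1] * state.entropy + bck[2] * kappa))
            if rec.deck_conf_report is not None:
                ll += _ordinal_logp_scalar(
                    c_k, params.sigma_k, params.theta_k, rec.deck_conf_report
                )
            _, a_hat = estimate_additional(report, c_k, params.epsilon, params.gamma)
            ll += _decision_terms(params, c_k, a_hat, rec, p_low)
            pointwise.append(ll)
            state = bayes_inference(state, rec.additional)
    pw = np.array(pointwise)
    return float(pw.sum()), pw
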