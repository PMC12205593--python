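"""Hierarchical Bayesian fitting, diagnostics, model comparison, recovery.

All individual-level parameters live on an unconstrained (raw) scale (see
:mod:`twentyone.models`) and are tied together by a normal hierarchy
``phi_ip ~ Normal(mu_p, tau_p)`` with weakly informative hyperpriors
(normal on the group means, half-normal(1) on the group SDs). Sampling
uses an adaptive Metropolis-within-Gibbs scheme: conjugate Gibbs updates
for the group means, adaptive random-walk Metropolis for the individual
parameters and the group SDs, with proposal scales tuned only during
burn-in. Convergence is assessed with rank-normalized split R-hat and
model comparison with PSIS-LOO (both via arviz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd

from ._math import sigmoid
from .dcmd import DCMDParams, PreparedSession, prepare_session
from .models import ModelSpec, dcmd_to_raw, get_model
from .synth import CohortSpec, _sample_raw
from .task import SessionData

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "AgreementReport",
    "fit_hierarchical",
    "gelman_rubin",
    "loo_compare",
    "map_agreement",
    "recover_parameters",
]

_TAU_PRIOR_SCALE = 1.0  # half-normal prior scale on group SDs
_TARGET_ACCEPT = 0.44   # optimal acceptance for scalar random-walk MH


@dataclass
class MCMCConfig:
    """Chain bookkeeping. Defaults follow the three-chain scheme of
    20,000 post-burn-in iterations, 10,000 burn-in, thinning 20 —
    3 x 1,000 = 3,000 retained draws."""

    n_chains: int = 3
    n_iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iterations < 1 or self.burn_in < 0:
            raise ValueError("chain counts and iterations must be positive")
        if self.n_iterations % self.thin:
            raise ValueError("n_iterations must be a multiple of thin")

    @property
    def draws_per_chain(self) -> int:
        return self.n_iterations // self.thin

    @property
    def total_draws(self) -> int:
        return self.n_chains * self.draws_per_chain


@dataclass
class PosteriorSamples:
    """Retained draws of a hierarchical fit plus pointwise log-likelihoods.

    ``mu``/``tau`` are (chain, draw, param); ``phi`` is (chain, draw,
    participant, param); ``log_likelihood`` is (chain, draw, trial) with
    one entry per trial (a trial's four report terms are summed).
    """

    model_id: str
    param_names: tuple[str, ...]
    participant_ids: tuple[str, ...]
    mu: np.ndarray
    tau: np.ndarray
    phi: np.ndarray
    log_likelihood: np.ndarray
    config: MCMCConfig
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for arr in (self.mu, self.tau, self.phi, self.log_likelihood):
            if not np.all(np.isfinite(arr)):
                raise ValueError("posterior contains nonfinite draws")

    def scalar_dict(self) -> dict[str, np.ndarray]:
        """Flatten to {scalar name: (chain, draw)} for diagnostics."""
        out: dict[str, np.ndarray] = {}
        for j, name in enumerate(self.param_names):
            out[f"mu_{name}"] = self.mu[:, :, j]
            out[f"tau_{name}"] = self.tau[:, :, j]
            for i, pid in enumerate(self.participant_ids):
                out[f"phi[{pid}]_{name}"] = self.phi[:, :, i, j]
        return out

    def to_inference_data(self) -> az.InferenceData:
        return az.from_dict(
            posterior=self.scalar_dict(),
            log_likelihood={"trial": self.log_likelihood},
        )

    def posterior_mean_phi(self) -> np.ndarray:
        """(participant, param) posterior means of individual raw vectors."""
        return self.phi.mean(axis=(0, 1))


def _participant_loglik(model: ModelSpec, raw: np.ndarray, prep: PreparedSession) -> float:
    try:
        ll = model.pointwise_loglik(raw, prep).sum()
    except (ValueError, FloatingPointError, OverflowError):
        return -np.inf
    return ll if np.isfinite(ll) else -np.inf


def _run_chain(
    model: ModelSpec,
    preps: list[PreparedSession],
    cfg: MCMCConfig,
    rng: np.random.Generator,
):
    n_part, n_par = len(preps), model.n_params
    prior_scale = model.prior_scales

    # overdispersed start
    mu = rng.normal(0.0, 1.0, n_par)
    tau = np.clip(np.abs(rng.normal(0.5, 0.2, n_par)), 0.1, None)
    phi = mu + rng.normal(0.0, 1.0, (n_part, n_par)) * tau
    cur_ll = np.array([_participant_loglik(model, phi[i], preps[i]) for i in range(n_part)])

    log_step_phi = np.full((n_part, n_par), np.log(0.2))
    log_step_tau = np.full(n_par, np.log(0.3))
    # per-participant adaptive-covariance joint proposal (Haario-style):
    # running mean/covariance of phi_i learned during burn-in
    am_mean = phi.copy()
    am_cov = np.tile(np.eye(n_par) * 0.01, (n_part, 1, 1))
    am_chol = np.tile(np.eye(n_par) * 0.1, (n_part, 1, 1))
    am_count = 0
    log_step_am = np.full(n_part, np.log(2.38 / np.sqrt(n_par)))
    n_draws = cfg.draws_per_chain
    mu_out = np.empty((n_draws, n_par))
    tau_out = np.empty((n_draws, n_par))
    phi_out = np.empty((n_draws, n_part, n_par))
    ll_out = np.empty((n_draws, sum(p.n_trials for p in preps)))
    n_divergent = 0

    total_iters = cfg.burn_in + cfg.n_iterations
    for it in range(total_iters):
        adapting = it < cfg.burn_in
        gain = 1.0 / (1.0 + it / 100.0) ** 0.6 if adapting else 0.0

        # individual parameters: scalar random-walk MH, one pass
        z = rng.normal(size=(n_part, n_par))
        log_u = np.log(rng.random((n_part, n_par)))
        for i in range(n_part):
            phi_i = phi[i]
            for p in range(n_par):
                prop = phi_i.copy()
                prop[p] += np.exp(log_step_phi[i, p]) * z[i, p]
                new_ll = _participant_loglik(model, prop, preps[i])
                if not np.isfinite(new_ll):
                    n_divergent += 1
                    accept = False
                else:
                    d_prior = (
                        (phi_i[p] - mu[p]) ** 2 - (prop[p] - mu[p]) ** 2
                    ) / (2.0 * tau[p] ** 2)
                    accept = log_u[i, p] < new_ll - cur_ll[i] + d_prior
                if accept:
                    phi_i[p] = prop[p]
                    cur_ll[i] = new_ll
                if adapting:
                    log_step_phi[i, p] += gain * ((1.0 if accept else 0.0) - _TARGET_ACCEPT)

        # joint adaptive-covariance proposals per participant
        for i in range(n_part):
            for _ in range(2):
                step = np.exp(log_step_am[i])
                prop = phi[i] + step * am_chol[i] @ rng.normal(size=n_par)
                new_ll = _participant_loglik(model, prop, preps[i])
                if np.isfinite(new_ll):
                    d_prior = (
                        ((phi[i] - mu) ** 2 - (prop - mu) ** 2) / (2.0 * tau**2)
                    ).sum()
                    accept = np.log(rng.random()) < new_ll - cur_ll[i] + d_prior
                else:
                    n_divergent += 1
                    accept = False
                if accept:
                    phi[i] = prop
                    cur_ll[i] = new_ll
                if adapting:
                    log_step_am[i] += gain * ((1.0 if accept else 0.0) - 0.23)

        # update running covariance; refresh Cholesky factors periodically
        if adapting:
            am_count += 1
            w = 1.0 / am_count
            delta = phi - am_mean
            am_mean += w * delta
            am_cov += w * (
                np.einsum("ij,ik->ijk", delta, phi - am_mean) - am_cov
            )
            if am_count >= 200 and it % 100 == 0:
                for i in range(n_part):
                    try:
                        am_chol[i] = np.linalg.cholesky(
                            am_cov[i] + 1e-6 * np.eye(n_par)
                        )
                    except np.linalg.LinAlgError:
                        pass

        # group means: conjugate Gibbs given phi, tau
        prec = n_part / tau**2 + 1.0 / prior_scale**2
        mean = (phi.sum(axis=0) / tau**2) / prec
        mu = mean + rng.normal(size=n_par) / np.sqrt(prec)

        # group SDs: random-walk on log tau with half-normal prior
        z_t = rng.normal(size=n_par)
        log_u_t = np.log(rng.random(n_par))
        prop_tau = tau * np.exp(np.exp(log_step_tau) * z_t)
        dev = ((phi - mu) ** 2).sum(axis=0)
        def _tau_logpost(t):
            return (
                -n_part * np.log(t)
                - dev / (2.0 * t**2)
                - t**2 / (2.0 * _TAU_PRIOR_SCALE**2)
                + np.log(t)  # Jacobian of the log transform
            )
        acc_t = log_u_t < _tau_logpost(prop_tau) - _tau_logpost(tau)
        tau = np.where(acc_t, prop_tau, tau)
        if adapting:
            log_step_tau += gain * (acc_t.astype(float) - _TARGET_ACCEPT)

        post = it - cfg.burn_in
        if post >= 0 and (post + 1) % cfg.thin == 0:
            d = post // cfg.thin
            mu_out[d] = mu
            tau_out[d] = tau
            phi_out[d] = phi
            ll_out[d] = np.concatenate(
                [model.pointwise_loglik(phi[i], preps[i]) for i in range(n_part)]
            )
    return mu_out, tau_out, phi_out, ll_out, n_divergent


def fit_hierarchical(
    model_id: str, sessions: list[SessionData], mcmc: MCMCConfig
) -> PosteriorSamples:
    """Fit a model hierarchically to one or more sessions.

    Returns the retained draws (chain bookkeeping per ``mcmc``) together
    with trial-level pointwise log-likelihoods for LOO. Proposals landing
    in nonfinite-likelihood regions are rejected and counted in
    ``diagnostics['n_divergent']``.
    """
    if not sessions:
        raise ValueError("at least one session is required")
    model = get_model(model_id)
    preps = [prepare_session(s) for s in sessions]
    root = np.random.SeedSequence(mcmc.seed)
    chains = [
        _run_chain(model, preps, mcmc, np.random.default_rng(child))
        for child in root.spawn(mcmc.n_chains)
    ]
    mu = np.stack([c[0] for c in chains])
    tau = np.stack([c[1] for c in chains])
    phi = np.stack([c[2] for c in chains])
    ll = np.stack([c[3] for c in chains])
    return PosteriorSamples(
        model_id=model_id,
        param_names=model.param_names,
        participant_ids=tuple(s.participant_id for s in sessions),
        mu=mu,
        tau=tau,
        phi=phi,
        log_likelihood=ll,
        config=mcmc,
        diagnostics={"n_divergent": int(sum(c[4] for c in chains))},
    )


def gelman_rubin(samples: PosteriorSamples) -> dict[str, float]:
    """Rank-normalized split R-hat per scalar parameter (arviz variant)."""
    if samples.mu.shape[0] < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least 2 chains")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.rhat(az.from_dict(posterior=samples.scalar_dict()))
    return {name: float(ds[name].values) for name in ds.data_vars}


def loo_compare(samples_per_model: dict[str, PosteriorSamples]) -> pd.DataFrame:
    """PSIS-LOO comparison table (LOOIC = -2 elpd_loo; lower is better).

    Rows are sorted best-first and carry the pairwise elpd difference to
    the best model and its SE (computed from the paired pointwise elpds).
    """
    n_obs = {mid: s.log_likelihood.shape[2] for mid, s in samples_per_model.items()}
    if len(set(n_obs.values())) > 1:
        raise ValueError(f"observation counts differ across models: {n_obs}")
    rows = {}
    pointwise = {}
    for mid, s in samples_per_model.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = az.loo(s.to_inference_data(), var_name="trial", pointwise=True)
        rows[mid] = {
            "elpd_loo": float(res.elpd_loo),
            "se": float(res.se),
            "p_loo": float(res.p_loo),
            "looic": -2.0 * float(res.elpd_loo),
        }
        pointwise[mid] = np.asarray(res.loo_i.values)
    table = pd.DataFrame(rows).T.sort_values("looic")
    best = table.index[0]
    diffs, dses = [], []
    for mid in table.index:
        d = pointwise[mid] - pointwise[best]
        diffs.append(float(d.sum()))
        n = d.shape[0]
        dses.append(float(np.sqrt(n * d.var(ddof=1))) if n > 1 else 0.0)
    table["elpd_diff"] = diffs
    table["diff_se"] = dses
    table["rank"] = range(len(table))
    return table


@dataclass
class AgreementReport:
    """Fractions of trials where the model's MAP prediction matches the
    observed report, per report type. ``None`` when no trials qualified."""

    fraction_deck: float | None
    fraction_deck_conf: float | None
    fraction_decision: float | None
    fraction_dec_conf: float | None
    n_deck: int
    n_deck_conf: int
    n_decision: int
    n_dec_conf: int


def _model_pmfs(model: ModelSpec, raw: np.ndarray, prep: PreparedSession):
    """Per-trial report pmfs at point parameters (observed reports drive
    the evidence and consistency recursions, as in fitting)."""
    from ._math import ordinal_report_pmf

    params = model.from_raw(raw)
    p6 = sigmoid(params.beta_k[0] + params.beta_k[1] * prep.delta_e)
    c_k = sigmoid(
        params.beta_ck[0]
        + params.beta_ck[1] * prep.abs_delta_e
        + params.beta_ck[2] * prep.kappa
    )
    deck_conf_pmf = ordinal_report_pmf(c_k, params.sigma_k, params.theta_k).T
    if isinstance(params, DCMDParams):
        omega = np.clip(params.epsilon - params.gamma * (1.0 - c_k), 0.0, 1.0)
        a_hat = omega * prep.e_rep + (1.0 - omega) * prep.e_alt
    else:
        a_hat = prep.e_rep
    v = 21.0 - (prep.faceup + prep.fd_exp + a_hat)
    u = params.beta_i[0] + params.beta_i[1] * v + params.beta_i[2] * v * np.abs(v)
    p_hit = sigmoid(u)
    ds = np.abs(u)
    if isinstance(params, DCMDParams):
        c_i = sigmoid(params.beta_ci[0] + params.beta_ci[1] * ds + params.beta_ci[2] * c_k)
    else:
        c_i = sigmoid(params.beta_ci[0] + params.beta_ci[1] * ds)
    dec_conf_pmf = ordinal_report_pmf(c_i, params.sigma_i, params.theta_i).T
    return p6, deck_conf_pmf, p_hit, dec_conf_pmf


def _argmax_tiebreak(pmf: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise argmax with uniform random tie-breaking."""
    best = pmf.max(axis=1, keepdims=True)
    ties = np.isclose(pmf, best)
    noise = rng.random(pmf.shape)
    return np.argmax(np.where(ties, noise, -1.0), axis=1)


def map_agreement(
    params,
    sessions: list[SessionData],
    seed: int = 0,
    model_id: str = "dcmd",
) -> AgreementReport:
    """Fraction of observed reports matched by MAP model predictions.

    ``params`` may be a fitted :class:`PosteriorSamples` (posterior-mean
    individual parameters are used), a single :class:`DCMDParams` / raw
    vector applied to every session, or a list of per-session parameter
    objects. Equally probable predictions are broken uniformly at random
    (seeded). Missing reports are excluded from the denominators.
    """
    model = get_model(model_id if not isinstance(params, PosteriorSamples) else params.model_id)
    if isinstance(params, PosteriorSamples):
        raws = list(params.posterior_mean_phi())
    elif isinstance(params, (list, tuple)):
        raws = [dcmd_to_raw(p) if isinstance(p, DCMDParams) else np.asarray(p) for p in params]
    elif isinstance(params, DCMDParams):
        raws = [dcmd_to_raw(params)] * len(sessions)
    else:
        raws = [np.asarray(params, dtype=float)] * len(sessions)
    if len(raws) != len(sessions):
        raise ValueError("parameter count does not match session count")

    rng = np.random.default_rng(seed)
    hits = np.zeros(4, dtype=int)
    ns = np.zeros(4, dtype=int)
    for raw, sess in zip(raws, sessions):
        prep = prepare_session(sess)
        p6, kc_pmf, p_hit, ic_pmf = _model_pmfs(model, raw, prep)
        deck_pred = _argmax_tiebreak(np.column_stack([1 - p6, p6]), rng)
        kc_pred = _argmax_tiebreak(kc_pmf, rng) + 1
        act_pred = _argmax_tiebreak(np.column_stack([1 - p_hit, p_hit]), rng)
        ic_pred = _argmax_tiebreak(ic_pmf, rng) + 1
        m = prep.deck_mask
        hits[0] += int((deck_pred[m] == prep.deck_is6[m]).sum()); ns[0] += int(m.sum())
        m = prep.deck_conf_mask
        hits[1] += int((kc_pred[m] == prep.deck_conf[m]).sum()); ns[1] += int(m.sum())
        m = prep.act_mask
        hits[2] += int((act_pred[m] == prep.hit[m]).sum()); ns[2] += int(m.sum())
        m = prep.dec_conf_mask
        hits[3] += int((ic_pred[m] == prep.dec_conf[m]).sum()); ns[3] += int(m.sum())
    frac = [h / n if n else None for h, n in zip(hits, ns)]
    return AgreementReport(
        fraction_deck=frac[0], fraction_deck_conf=frac[1],
        fraction_decision=frac[2], fraction_dec_conf=frac[3],
        n_deck=int(ns[0]), n_deck_conf=int(ns[1]),
        n_decision=int(ns[2]), n_dec_conf=int(ns[3]),
    )


def recover_parameters(
    spec: CohortSpec,
    mcmc: MCMCConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """End-to-end parameter recovery: simulate a cohort from known group
    parameters, refit hierarchically, and compare posterior to truth.

    The report carries, per individual-level parameter (raw scale): the
    correlation between true and posterior-mean individual values, the mean
    bias, and the coverage of the central 95% credible intervals; plus
    group-mean coverage and the maximum split R-hat. Plots are written to
    ``out_dir`` when given.
    """
    true_raw, _, sessions = _sample_raw(spec)
    samples = fit_hierarchical("dcmd", sessions, mcmc)
    names = samples.param_names
    post_mean = samples.posterior_mean_phi()
    flat_phi = samples.phi.reshape(-1, *samples.phi.shape[2:])  # (draws, part, par)
    lo = np.percentile(flat_phi, 2.5, axis=0)
    hi = np.percentile(flat_phi, 97.5, axis=0)
    rows = []
    for j, name in enumerate(names):
        t, m = true_raw[:, j], post_mean[:, j]
        corr = float(np.corrcoef(t, m)[0, 1]) if len(t) > 1 else np.nan
        rows.append({
            "parameter": name,
            "correlation": corr,
            "bias": float((m - t).mean()),
            "coverage95": float(((lo[:, j] <= t) & (t <= hi[:, j])).mean()),
        })
    individual = pd.DataFrame(rows)

    flat_mu = samples.mu.reshape(-1, samples.mu.shape[2])
    mu_lo = np.percentile(flat_mu, 2.5, axis=0)
    mu_hi = np.percentile(flat_mu, 97.5, axis=0)
    true_mu = spec.group.mu_vector(names)
    group = pd.DataFrame({
        "parameter": names,
        "true_mu": true_mu,
        "posterior_mean": flat_mu.mean(axis=0),
        "ci_lo": mu_lo,
        "ci_hi": mu_hi,
        "covered": (mu_lo <= true_mu) & (true_mu <= mu_hi),
    })
    rhat = gelman_rubin(samples)
    report = {
        "individual": individual,
        "group": group,
        "max_rhat": max(rhat.values()),
        "samples": samples,
        "true_raw": true_raw,
    }
    if out_dir is not None:
        _plot_recovery(report, names, post_mean, true_raw, Path(out_dir))
    return report


def _plot_recovery(report, names, post_mean, true_raw, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    n = len(names)
    ncol = 5
    nrow = -(-n // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow))
    for j, (name, ax) in enumerate(zip(names, axes.ravel())):
        ax.scatter(true_raw[:, j], post_mean[:, j], s=12)
        lims = [min(true_raw[:, j].min(), post_mean[:, j].min()),
                max(true_raw[:, j].max(), post_mean[:, j].max())]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_title(name, fontsize=9)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.suptitle("true vs. posterior-mean individual parameters (raw scale)")
    fig.tight_layout()
    fig.savefig(out_dir / "recovery_scatter.png", dpi=100)
    plt.close(fig)
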