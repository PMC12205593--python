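"""Registry mapping model ids to parameterizations and likelihoods.

Each fittable model exposes its individual-level parameters on an
*unconstrained* (raw) scale so that the hierarchy "individual ~
Normal(group mean, group SD)" can hold without violating bounds:

* report-noise scales: ``sigma = exp(raw)``
* ordinal thresholds: ``theta_1|2 = 0.5 - exp(raw_lo)``,
  ``theta_3|4 = 0.5 + exp(raw_hi)`` (middle threshold fixed at 0.5)
* ``epsilon = 0.5 + 0.5 sigmoid(raw)`` (so epsilon in (0.5, 1))
* ``gamma = 0.5 sigmoid(raw)`` (so gamma in (0, 0.5) < epsilon)
* regression weights are untransformed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit, logit

from . import _kernels
from .alternatives import DCIDParams, dcid_pointwise_loglik
from .dcmd import DCMDParams, PreparedSession, _pointwise_loglik

__all__ = ["ModelSpec", "MODELS", "get_model"]

_WEIGHT_SCALE = 5.0   # prior SD of group means of regression weights
_TRANSFORM_SCALE = 2.0  # prior SD of group means of transformed parameters

_DCMD_NAMES = [
    "bk0", "bk1", "bck0", "bck1", "bck2", "log_sigma_k", "thk_lo", "thk_hi",
    "bi0", "bi1", "bi2", "bci0", "bci1", "bci2",
    "eps_raw", "gam_raw", "log_sigma_i", "thi_lo", "thi_hi",
]
_DCID_NAMES = [
    "bk0", "bk1", "bck0", "bck1", "bck2", "log_sigma_k", "thk_lo", "thk_hi",
    "bi0", "bi1", "bi2", "bci0", "bci1",
    "log_sigma_i", "thi_lo", "thi_hi",
]

_TRANSFORMED = {"log_sigma_k", "log_sigma_i", "thk_lo", "thk_hi",
                "thi_lo", "thi_hi", "eps_raw", "gam_raw"}


def _prior_scales(names: list[str]) -> np.ndarray:
    return np.array(
        [_TRANSFORM_SCALE if n in _TRANSFORMED else _WEIGHT_SCALE for n in names]
    )


def _thresholds(lo: float, hi: float) -> np.ndarray:
    return np.array([0.5 - np.exp(lo), 0.5, 0.5 + np.exp(hi)])


def dcmd_from_raw(raw: np.ndarray) -> DCMDParams:
    r = dict(zip(_DCMD_NAMES, np.asarray(raw, dtype=float)))
    return DCMDParams(
        beta_k=[r["bk0"], r["bk1"]],
        beta_ck=[r["bck0"], r["bck1"], r["bck2"]],
        epsilon=float(0.5 + 0.5 * expit(r["eps_raw"])),
        gamma=float(0.5 * expit(r["gam_raw"])),
        beta_i=[r["bi0"], r["bi1"], r["bi2"]],
        beta_ci=[r["bci0"], r["bci1"], r["bci2"]],
        sigma_k=float(np.exp(r["log_sigma_k"])),
        sigma_i=float(np.exp(r["log_sigma_i"])),
        theta_k=_thresholds(r["thk_lo"], r["thk_hi"]),
        theta_i=_thresholds(r["thi_lo"], r["thi_hi"]),
    )


def dcmd_to_raw(p: DCMDParams) -> np.ndarray:
    return np.array([
        p.beta_k[0], p.beta_k[1],
        p.beta_ck[0], p.beta_ck[1], p.beta_ck[2],
        np.log(p.sigma_k),
        np.log(0.5 - p.theta_k[0]), np.log(p.theta_k[2] - 0.5),
        p.beta_i[0], p.beta_i[1], p.beta_i[2],
        p.beta_ci[0], p.beta_ci[1], p.beta_ci[2],
        logit((p.epsilon - 0.5) / 0.5), logit(p.gamma / 0.5),
        np.log(p.sigma_i),
        np.log(0.5 - p.theta_i[0]), np.log(p.theta_i[2] - 0.5),
    ])


def dcid_from_raw(raw: np.ndarray) -> DCIDParams:
    r = dict(zip(_DCID_NAMES, np.asarray(raw, dtype=float)))
    return DCIDParams(
        beta_k=[r["bk0"], r["bk1"]],
        beta_ck=[r["bck0"], r["bck1"], r["bck2"]],
        beta_i=[r["bi0"], r["bi1"], r["bi2"]],
        beta_ci=[r["bci0"], r["bci1"]],
        sigma_k=float(np.exp(r["log_sigma_k"])),
        sigma_i=float(np.exp(r["log_sigma_i"])),
        theta_k=_thresholds(r["thk_lo"], r["thk_hi"]),
        theta_i=_thresholds(r["thi_lo"], r["thi_hi"]),
    )


@dataclass(frozen=True)
class ModelSpec:
    """A fittable model: raw-scale parameter names, the raw-to-constrained
    map, a vectorized pointwise log-likelihood, and hyperprior scales."""

    model_id: str
    param_names: tuple[str, ...]
    from_raw: Callable
    pointwise_loglik: Callable  # (raw vector, PreparedSession) -> (n_trials,)
    prior_scales: np.ndarray

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _kernel_args(prep: PreparedSession) -> tuple:
    cached = getattr(prep, "_kernel_args", None)
    if cached is None:
        cached = (
            prep.delta_e, prep.abs_delta_e, prep.kappa, prep.e_rep, prep.e_alt,
            prep.faceup, prep.fd_exp,
            prep.deck_is6, prep.deck_mask, prep.hit, prep.act_mask,
            prep.deck_conf, prep.deck_conf_mask, prep.dec_conf, prep.dec_conf_mask,
        )
        prep._kernel_args = cached  # type: ignore[attr-defined]
    return cached


if _kernels.HAVE_NUMBA:

    def _dcmd_pointwise(raw: np.ndarray, prep: PreparedSession) -> np.ndarray:
        return _kernels.dcmd_pointwise_kernel(np.asarray(raw, float), *_kernel_args(prep))

    def _dcid_pointwise(raw: np.ndarray, prep: PreparedSession) -> np.ndarray:
        return _kernels.dcid_pointwise_kernel(np.asarray(raw, float), *_kernel_args(prep))

else:  # pragma: no cover - exercised only without numba

    def _dcmd_pointwise(raw: np.ndarray, prep: PreparedSession) -> np.ndarray:
        return _pointwise_loglik(prep, dcmd_from_raw(raw))

    def _dcid_pointwise(raw: np.ndarray, prep: PreparedSession) -> np.ndarray:
        return dcid_pointwise_loglik(prep, dcid_from_raw(raw))


MODELS: dict[str, ModelSpec] = {
    "dcmd": ModelSpec(
        "dcmd", tuple(_DCMD_NAMES), dcmd_from_raw, _dcmd_pointwise,
        _prior_scales(_DCMD_NAMES),
    ),
    "dcid": ModelSpec(
        "dcid", tuple(_DCID_NAMES), dcid_from_raw, _dcid_pointwise,
        _prior_scales(_DCID_NAMES),
    ),
}


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise ValueError(
            f"unknown or non-fittable model {model_id!r}; "
            f"hierarchically fittable models: {sorted(MODELS)}"
        ) from None
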