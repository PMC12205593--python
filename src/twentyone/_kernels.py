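"""JIT-compiled per-trial likelihood kernels for the MCMC hot path.

These mirror :func:`twentyone.dcmd._pointwise_loglik` and
:func:`twentyone.alternatives.dcid_pointwise_loglik` exactly (a regression
test asserts agreement); the vectorized numpy versions remain the readable
reference implementation and the fallback when numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


_LOG_TINY = math.log(1e-300)
_SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _log_sigmoid(x: float) -> float:
    if x >= 0.0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


@njit(cache=True)
def _sigmoid(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _phi(x: float) -> float:
    # erfc form keeps precision in the lower tail
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True)
def _ordinal_logp(c: float, sigma: float, th1: float, th3: float, report: int) -> float:
    if report == 1:
        p = _phi((th1 - c) / sigma)
    elif report == 2:
        p = _phi((0.5 - c) / sigma) - _phi((th1 - c) / sigma)
    elif report == 3:
        p = _phi((th3 - c) / sigma) - _phi((0.5 - c) / sigma)
    else:
        p = 1.0 - _phi((th3 - c) / sigma)
    if p <= 1e-300:
        return _LOG_TINY
    return math.log(p)


@njit(cache=True)
def dcmd_pointwise_kernel(
    raw,
    delta_e, abs_de, kappa, e_rep, e_alt, faceup, fd_exp,
    deck_is6, deck_mask, hit, act_mask,
    deck_conf, deck_conf_mask, dec_conf, dec_conf_mask,
):
    bk0, bk1 = raw[0], raw[1]
    bck0, bck1, bck2 = raw[2], raw[3], raw[4]
    sigma_k = math.exp(raw[5])
    thk1, thk3 = 0.5 - math.exp(raw[6]), 0.5 + math.exp(raw[7])
    bi0, bi1, bi2 = raw[8], raw[9], raw[10]
    bci0, bci1, bci2 = raw[11], raw[12], raw[13]
    eps = 0.5 + 0.5 * _sigmoid(raw[14])
    gam = 0.5 * _sigmoid(raw[15])
    sigma_i = math.exp(raw[16])
    thi1, thi3 = 0.5 - math.exp(raw[17]), 0.5 + math.exp(raw[18])

    n = delta_e.shape[0]
    out = np.empty(n)
    for t in range(n):
        ll = 0.0
        logit_p6 = bk0 + bk1 * delta_e[t]
        if deck_mask[t]:
            ll += _log_sigmoid(logit_p6) if deck_is6[t] == 1 else _log_sigmoid(-logit_p6)
        c_k = _sigmoid(bck0 + bck1 * abs_de[t] + bck2 * kappa[t])
        if deck_conf_mask[t]:
            ll += _ordinal_logp(c_k, sigma_k, thk1, thk3, deck_conf[t])
        omega = eps - gam * (1.0 - c_k)
        if omega < 0.0:
            omega = 0.0
        elif omega > 1.0:
            omega = 1.0
        a_hat = omega * e_rep[t] + (1.0 - omega) * e_alt[t]
        v = 21.0 - (faceup[t] + fd_exp[t] + a_hat)
        u = bi0 + bi1 * v + bi2 * v * abs(v)
        if act_mask[t]:
            ll += _log_sigmoid(u) if hit[t] == 1 else _log_sigmoid(-u)
        if dec_conf_mask[t]:
            c_i = _sigmoid(bci0 + bci1 * abs(u) + bci2 * c_k)
            ll += _ordinal_logp(c_i, sigma_i, thi1, thi3, dec_conf[t])
        out[t] = ll
    return out


@njit(cache=True)
def dcid_pointwise_kernel(
    raw,
    delta_e, abs_de, kappa, e_rep, e_alt, faceup, fd_exp,
    deck_is6, deck_mask, hit, act_mask,
    deck_conf, deck_conf_mask, dec_conf, dec_conf_mask,
):
    bk0, bk1 = raw[0], raw[1]
    bck0, bck1, bck2 = raw[2], raw[3], raw[4]
    sigma_k = math.exp(raw[5])
    thk1, thk3 = 0.5 - math.exp(raw[6]), 0.5 + math.exp(raw[7])
    bi0, bi1, bi2 = raw[8], raw[9], raw[10]
    bci0, bci1 = raw[11], raw[12]
    sigma_i = math.exp(raw[13])
    thi1, thi3 = 0.5 - math.exp(raw[14]), 0.5 + math.exp(raw[15])

    n = delta_e.shape[0]
    out = np.empty(n)
    for t in range(n):
        ll = 0.0
        logit_p6 = bk0 + bk1 * delta_e[t]
        if deck_mask[t]:
            ll += _log_sigmoid(logit_p6) if deck_is6[t] == 1 else _log_sigmoid(-logit_p6)
        c_k = _sigmoid(bck0 + bck1 * abs_de[t] + bck2 * kappa[t])
        if deck_conf_mask[t]:
            ll += _ordinal_logp(c_k, sigma_k, thk1, thk3, deck_conf[t])
        v = 21.0 - (faceup[t] + fd_exp[t] + e_rep[t])
        u = bi0 + bi1 * v + bi2 * v * abs(v)
        if act_mask[t]:
            ll += _log_sigmoid(u) if hit[t] == 1 else _log_sigmoid(-u)
        if dec_conf_mask[t]:
            c_i = _sigmoid(bci0 + bci1 * abs(u))
            ll += _ordinal_logp(c_i, sigma_i, thi1, thi3, dec_conf[t])
        out[t] = ll
    return out
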