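"""Shared numerical primitives: logistic links and ordinal-probit reports."""

from __future__ import annotations

import numpy as np
from scipy.special import expit, log_expit, ndtr

_TINY = 1e-300


def sigmoid(x):
    return expit(x)


def log_bernoulli(event: np.ndarray, logit_p: np.ndarray) -> np.ndarray:
    """log P(event) for event ~ Bernoulli(sigmoid(logit_p)), vectorized."""
    return np.where(event.astype(bool), log_expit(logit_p), log_expit(-logit_p))


def check_thresholds(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (3,):
        raise ValueError("theta must be a (theta_1|2, theta_2|3, theta_3|4) triple")
    if not (theta[0] < theta[1] < theta[2]):
        raise ValueError(f"thresholds must be strictly increasing, got {theta}")
    return theta


def ordinal_report_pmf(c, sigma: float, theta) -> np.ndarray:
    """pmf over 4-point reports of a graded confidence ``c`` in (0, 1).

    The report is modeled as ``c`` plus N(0, sigma^2) noise cut at the three
    thresholds: P(C=k) = Phi((theta_k|k+1 - c)/sigma) - Phi((theta_k-1|k - c)/sigma).
    """
    theta = check_thresholds(theta)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    c = np.asarray(c, dtype=float)
    z = ndtr((theta.reshape((3,) + (1,) * c.ndim) - c) / sigma)  # (3, ...)
    p1 = z[0]
    p2 = z[1] - z[0]
    p3 = z[2] - z[1]
    p4 = 1.0 - z[2]
    return np.stack([p1, p2, p3, p4], axis=0) if c.ndim else np.array([p1, p2, p3, p4])


def ordinal_report_logpmf_at(
    c: np.ndarray, sigma: float, theta: np.ndarray, reports: np.ndarray
) -> np.ndarray:
    """log P(report) per trial; ``reports`` are 1..4 (entries at masked trials
    may be arbitrary in 1..4). No threshold re-validation: hot path."""
    z = ndtr((theta[:, None] - c[None, :]) / sigma)  # (3, n)
    cdf = np.vstack([np.zeros_like(c)[None, :], z, np.ones_like(c)[None, :]])  # (5, n)
    idx = np.arange(c.shape[0])
    p = cdf[reports, idx] - cdf[reports - 1, idx]
    return np.log(np.maximum(p, _TINY))
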