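"""Descriptive behavioral analyses of twenty-one sessions.

Everything here is a pure function of a tidy trial table (one row per
trial) plus explicit options: confidence-conditioned accuracy curves,
participant-specific mean splits, shift/slope logistic psychometric fits
of the hit probability against the face-up score, V-shaped decision
confidence fits, and the joint confidence matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .task import DeckType, SessionData, resolve_payoff

__all__ = [
    "LogisticFit",
    "sessions_frame",
    "mean_split",
    "fit_shift_slope",
    "condition_fits",
    "confidence_accuracy_curves",
    "joint_confidence_matrix",
    "decision_conf_bias_fit",
]

_SLOPE_CAP = 10.0  # |slope| above this is treated as separation, not reported


@dataclass
class LogisticFit:
    """Psychometric fit P(hit) = logistic(slope * (faceup - shift))."""

    slope: float
    shift: float
    n_obs: int
    converged: bool


def sessions_frame(sessions: list[SessionData]) -> pd.DataFrame:
    """Tidy per-trial table with derived columns used by the analyses.

    ``higher_reward`` marks trials whose chosen action realized a payoff at
    least as large as the alternative's (computable on every trial because
    both hidden cards are always revealed); ties favor the chosen action.
    """
    rows = []
    for sess in sessions:
        for config, rec in sess.iter_trials():
            if rec.action is not None:
                pay_hit = resolve_payoff(rec.faceup, rec.facedown, rec.additional, "hit")
                pay_stay = resolve_payoff(rec.faceup, rec.facedown, rec.additional, "stay")
                chosen = pay_hit if rec.action == "hit" else pay_stay
                other = pay_stay if rec.action == "hit" else pay_hit
                higher = chosen >= other
            else:
                higher = None
            rows.append({
                "participant": sess.participant_id,
                "game": rec.game_index,
                "trial": rec.trial_index,
                "true_deck": config.additional_deck.value,
                "faceup": rec.faceup,
                "deck_report": rec.deck_report.value if rec.deck_report else None,
                "deck_correct": (
                    rec.deck_report is config.additional_deck
                    if rec.deck_report is not None else None
                ),
                "deck_conf": rec.deck_conf_report,
                "hit": 1 if rec.action == "hit" else (0 if rec.action == "stay" else None),
                "dec_conf": rec.dec_conf_report,
                "higher_reward": higher,
                "payoff": rec.payoff,
            })
    return pd.DataFrame(rows)


def mean_split(values: pd.Series, by: pd.Series) -> pd.Series:
    """Label each value 'high' or 'low' relative to its participant's mean.

    Ties (value exactly equal to the mean) are labeled low. Missing values
    stay missing; participants with no non-missing values are excluded with
    a warning.
    """
    means = values.groupby(by).transform("mean")
    empty = values.groupby(by).count() == 0
    if empty.any():
        warnings.warn(
            f"participants with all-missing values excluded from mean split: "
            f"{list(empty[empty].index)}"
        )
    out = pd.Series(
        np.where(values > means, "high", "low"), index=values.index, dtype=object
    )
    out[values.isna()] = None
    return out


def fit_shift_slope(
    faceup,
    hit,
    participant=None,
    pooling: str = "participant",
) -> LogisticFit:
    """Fit P(hit) = logistic(slope * (faceup - shift)).

    ``pooling='participant'`` is a plain ML logistic fit of the pooled
    trials. ``pooling='hierarchical'`` fits each participant separately and
    partially pools the estimates toward the group mean by inverse-variance
    (normal-normal) shrinkage; the returned fit is the group-level mean and
    per-participant shrunk estimates are attached as ``fit.per_participant``.
    Non-convergence (separation, a single response class, fewer than two
    distinct face-up values) yields ``converged=False``.
    """
    faceup = np.asarray(faceup, dtype=float)
    hit = np.asarray(hit, dtype=float)
    if pooling == "participant":
        return _ml_shift_slope(faceup, hit)
    if pooling != "hierarchical":
        raise ValueError(f"unknown pooling {pooling!r}")
    if participant is None:
        raise ValueError("hierarchical pooling requires participant labels")
    participant = np.asarray(participant)
    fits = {}
    for pid in pd.unique(participant):
        m = participant == pid
        fits[pid] = _ml_shift_slope(faceup[m], hit[m])
    good = {pid: f for pid, f in fits.items() if f.converged}
    if not good:
        return LogisticFit(np.nan, np.nan, int(len(faceup)), False)
    slopes = np.array([f.slope for f in good.values()])
    shifts = np.array([f.shift for f in good.values()])
    shrunk = {}
    for (pid, f), sl, sh in zip(good.items(), _shrink(slopes), _shrink(shifts)):
        shrunk[pid] = LogisticFit(float(sl), float(sh), f.n_obs, True)
    group = LogisticFit(
        float(np.mean([f.slope for f in shrunk.values()])),
        float(np.mean([f.shift for f in shrunk.values()])),
        int(len(faceup)),
        True,
    )
    group.per_participant = shrunk  # type: ignore[attr-defined]
    return group


def _shrink(est: np.ndarray) -> np.ndarray:
    """James-Stein-style shrinkage toward the group mean."""
    if est.size < 3:
        return est
    grand = est.mean()
    var_between = est.var(ddof=1)
    if var_between == 0:
        return est
    # shrink by the fraction of variance attributable to noise, estimated
    # from the spread itself (conservative: 1/n of between variance)
    w = 1.0 / est.size
    return grand + (1.0 - w) * (est - grand)


def _ml_shift_slope(faceup: np.ndarray, hit: np.ndarray) -> LogisticFit:
    n = int(len(faceup))
    distinct = np.unique(faceup)
    if n < 2 or len(distinct) < 2 or hit.min() == hit.max():
        return LogisticFit(np.nan, np.nan, n, False)
    X = sm.add_constant(faceup)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(hit, X).fit(disp=0, maxiter=200)
        except Exception:
            return LogisticFit(np.nan, np.nan, n, False)
    b0, b1 = res.params
    if not np.all(np.isfinite(res.params)) or abs(b1) > _SLOPE_CAP or b1 == 0:
        return LogisticFit(np.nan, np.nan, n, False)
    return LogisticFit(float(b1), float(-b0 / b1), n, True)


def condition_fits(
    sessions: list[SessionData], split_variable: str = "dec_conf"
) -> pd.DataFrame:
    """Per-participant shift/slope fits in the 2x2 cells deck report
    (4/6) x high/low confidence (participant-specific mean split of
    ``split_variable``, 'deck_conf' or 'dec_conf')."""
    if split_variable not in ("deck_conf", "dec_conf"):
        raise ValueError("split_variable must be 'deck_conf' or 'dec_conf'")
    df = sessions_frame(sessions)
    df = df.dropna(subset=["deck_report", split_variable, "hit", "faceup"])
    df = df.copy()
    df["conf_split"] = mean_split(df[split_variable], df["participant"])
    rows = []
    for (pid, deck, level), sub in df.groupby(["participant", "deck_report", "conf_split"]):
        fit = _ml_shift_slope(sub["faceup"].to_numpy(float), sub["hit"].to_numpy(float))
        rows.append({
            "participant": pid,
            "deck_report": deck,
            "confidence": level,
            "slope": fit.slope,
            "shift": fit.shift,
            "n_obs": fit.n_obs,
            "converged": fit.converged,
        })
    out = pd.DataFrame(rows)
    if out.empty:
        warnings.warn("no cells with data for condition fits")
    return out


def confidence_accuracy_curves(sessions: list[SessionData]) -> dict:
    """Deck-report accuracy by deck-confidence level and higher-reward
    choice rate by decision-confidence level, with group- and
    participant-level Pearson correlations."""
    df = sessions_frame(sessions)

    def _tables(value_col, level_col):
        sub = df.dropna(subset=[value_col, level_col])
        per_part = (
            sub.groupby(["participant", level_col])[value_col]
            .mean()
            .rename("rate")
            .reset_index()
        )
        group_r = _safe_corr(per_part[level_col], per_part["rate"])
        indiv = []
        for pid, s in sub.groupby("participant"):
            indiv.append(_safe_corr(s[level_col], s[value_col].astype(float)))
        return per_part, group_r, float(np.nanmean(indiv)) if indiv else np.nan

    deck_tab, deck_group_r, deck_indiv_r = _tables("deck_correct", "deck_conf")
    dec_tab, dec_group_r, dec_indiv_r = _tables("higher_reward", "dec_conf")
    return {
        "deck_accuracy": deck_tab,
        "deck_group_r": deck_group_r,
        "deck_individual_r": deck_indiv_r,
        "higher_reward": dec_tab,
        "dec_group_r": dec_group_r,
        "dec_individual_r": dec_indiv_r,
        "chance_level": 0.5,
    }


def _safe_corr(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def joint_confidence_matrix(sessions: list[SessionData]) -> dict:
    """4x4 joint proportion matrix of (deck confidence, decision
    confidence) reports, their Pearson correlation, and the fraction of
    trials where the two reports differ."""
    df = sessions_frame(sessions).dropna(subset=["deck_conf", "dec_conf"])
    mat = np.zeros((4, 4))
    for k, i in zip(df["deck_conf"].astype(int), df["dec_conf"].astype(int)):
        mat[i - 1, k - 1] += 1  # rows: decision confidence; cols: deck confidence
    n = mat.sum()
    return {
        "matrix": mat / n if n else mat,
        "correlation": _safe_corr(df["deck_conf"], df["dec_conf"]),
        "disagreement": float((df["deck_conf"] != df["dec_conf"]).mean()) if n else np.nan,
        "n_trials": int(n),
    }


def decision_conf_bias_fit(sessions: list[SessionData]) -> dict:
    """V-shaped fits of decision confidence against the face-up score.

    Decision confidence is lowest near the face-up score where hitting and
    staying are equally attractive and rises on either side. Per
    participant, the vertex is anchored at the face-up score minimizing the
    participant's mean decision confidence; per deck-confidence level a
    linear model ``conf = bias + slope |faceup - vertex|`` is then fit.
    Returns the per-level table and the correlation of the fitted bias with
    deck-confidence level.
    """
    df = sessions_frame(sessions).dropna(subset=["dec_conf", "deck_conf", "faceup"])
    rows = []
    for pid, sub in df.groupby("participant"):
        prof = sub.groupby("faceup")["dec_conf"].mean()
        vertex = float(prof.idxmin())
        for level, s in sub.groupby("deck_conf"):
            if len(s) < 3:
                warnings.warn(f"participant {pid}, level {level}: too few trials")
                continue
            x = np.abs(s["faceup"].to_numpy(float) - vertex)
            y = s["dec_conf"].to_numpy(float)
            if np.std(x) == 0:
                continue
            slope, bias = np.polyfit(x, y, 1)
            rows.append({
                "participant": pid,
                "deck_conf": int(level),
                "vertex": vertex,
                "slope": float(slope),
                "bias": float(bias),
                "n_obs": int(len(s)),
            })
    table = pd.DataFrame(rows)
    corr = _safe_corr(table["deck_conf"], table["bias"]) if len(table) else np.nan
    return {"fits": table, "bias_conf_correlation": corr}
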