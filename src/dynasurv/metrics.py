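"""Dynamic-prediction evaluation: conditional risk, IPCW tdAUC and Brier score.

All metrics operate on the conditional risk of an event in (l, t] given
survival to the landmark l, R(t|l) = 1 - S(t)/S(l).  Right censoring is
handled by inverse-probability-of-censoring weights 1/G(T), where G is the
Kaplan-Meier estimate of the censoring survival function computed from the
*training* data (censoring, 1 - delta, plays the role of the event).  For
simulated data the exact risk from the generator is available, so the mean
squared error against the truth can be computed as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SimulationTruth
from .survival import SurvivalCurves

__all__ = [
    "CensoringDistribution",
    "censoring_km",
    "conditional_risk",
    "tdauc_ipcw",
    "brier_ipcw",
    "mse_vs_truth",
    "oracle_reference_metrics",
    "true_risks",
]


@dataclass(frozen=True)
class CensoringDistribution:
    """Kaplan-Meier estimate of the censoring survival function G(t)."""

    step_times: np.ndarray  # distinct observed times with censorings
    values: np.ndarray  # G immediately after each step time

    def at(self, t) -> np.ndarray:
        """G(t), right-continuous."""
        if len(self.step_times) == 0:
            return np.ones_like(np.asarray(t, float))
        idx = np.searchsorted(self.step_times, np.asarray(t, float), side="right") - 1
        return np.where(idx >= 0, self.values[np.clip(idx, 0, len(self.values) - 1)], 1.0)

    def at_left(self, t) -> np.ndarray:
        """Left limit G(t-): probability of being uncensored just before t."""
        if len(self.step_times) == 0:
            return np.ones_like(np.asarray(t, float))
        idx = np.searchsorted(self.step_times, np.asarray(t, float), side="left") - 1
        return np.where(idx >= 0, self.values[np.clip(idx, 0, len(self.values) - 1)], 1.0)


def censoring_km(times, events) -> CensoringDistribution:
    """KM product over the training observations with censoring as the event:
    G(t) = prod_{t_j <= t} (1 - #censored(t_j) / #at-risk(t_j))."""
    times = np.asarray(times, float)
    cens = 1 - np.asarray(events).astype(int)
    order = np.argsort(times, kind="mergesort")
    times, cens = times[order], cens[order]
    uniq = np.unique(times)
    at_risk = len(times) - np.searchsorted(times, uniq, side="left")
    d_c = np.array([cens[times == t].sum() for t in uniq])
    keep = d_c > 0
    if not keep.any():
        return CensoringDistribution(np.zeros(0), np.ones(0))
    factors = 1.0 - d_c[keep] / at_risk[keep]
    return CensoringDistribution(uniq[keep], np.cumprod(factors))


def conditional_risk(curves: SurvivalCurves, l: float, t: float) -> np.ndarray:
    """Predicted risk R(t|l) = 1 - S(t)/S(l) per subject (NaN if S(l) = 0)."""
    if t < l:
        raise ValueError("horizon t must be >= landmark l")
    s_l = curves.at(l)
    s_t = curves.at(t)
    bad = s_l <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} subjects have S(l)=0; excluded (NaN risk)",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 1.0 - s_t / s_l
    r[bad] = np.nan
    return np.clip(r, 0.0, 1.0, out=r, where=~bad)


def _split_cases(times, events, horizon):
    times = np.asarray(times, float)
    events = np.asarray(events).astype(int)
    cases = (events == 1) & (times <= horizon)
    controls = times > horizon
    return cases, controls


def tdauc_ipcw(risk, times, events, G: CensoringDistribution, horizon: float,
               strict_ties: bool = False) -> float:
    """IPCW time-dependent AUC at ``horizon``.

    Weighted proportion of (case, control) pairs ranked correctly, with case
    weights 1/G(T_i-); ties in the predicted risk count 1/2 unless
    ``strict_ties`` (the literal strict-inequality indicator) is requested.
    Returns NaN when there are no cases or no controls.
    """
    risk = np.asarray(risk, float)
    cases, controls = _split_cases(times, events, horizon)
    valid = ~np.isnan(risk)
    cases &= valid
    controls &= valid
    if not cases.any() or not controls.any():
        warnings.warn("tdAUC undefined: no cases or no controls at this horizon",
                      stacklevel=2)
        return float("nan")
    g = G.at_left(np.asarray(times, float)[cases])
    pos = g > 0
    if not pos.all():
        warnings.warn(f"excluding {int((~pos).sum())} cases with G(T-)=0", stacklevel=2)
    w = np.where(pos, 1.0 / np.where(pos, g, 1.0), 0.0)
    rc = risk[cases][:, None]
    rj = risk[controls][None, :]
    correct = (rc > rj).astype(float)
    if not strict_ties:
        correct += 0.5 * (rc == rj)
    num = (w[:, None] * correct).sum()
    den = w.sum() * controls.sum()
    return float(num / den)


def brier_ipcw(risk, times, events, G: CensoringDistribution, horizon: float) -> float:
    """IPCW Brier score at ``horizon``: mean over subjects of
    delta.1(T<=t)(1-R)^2/G(T-) + 1(T>t)R^2/G(t); censored-before-t subjects
    contribute zero."""
    risk = np.asarray(risk, float)
    times = np.asarray(times, float)
    events = np.asarray(events).astype(int)
    n = len(times)
    had_event = (events == 1) & (times <= horizon)
    survivor = times > horizon
    terms = np.zeros(n)
    g_event = G.at_left(times[had_event])
    pos = g_event > 0
    if not pos.all():
        warnings.warn(f"excluding {int((~pos).sum())} event terms with G(T-)=0",
                      stacklevel=2)
    r_ev = risk[had_event]
    terms[had_event] = np.where(pos & ~np.isnan(r_ev),
                                (1.0 - r_ev) ** 2 / np.where(pos, g_event, 1.0), 0.0)
    g_t = float(G.at(horizon))
    if survivor.any():
        if g_t <= 0:
            warnings.warn("G(t)=0 at the horizon; survivor terms excluded", stacklevel=2)
        else:
            r_s = risk[survivor]
            terms[survivor] = np.where(np.isnan(r_s), 0.0, r_s**2) / g_t
    return float(terms.sum() / n)


def mse_vs_truth(risk_hat, risk_true) -> float:
    """Mean squared error of predicted vs true conditional risks."""
    risk_hat = np.asarray(risk_hat, float)
    risk_true = np.asarray(risk_true, float)
    if risk_true.shape != risk_hat.shape:
        raise ValueError("risk vectors must have equal length")
    ok = ~np.isnan(risk_hat)
    return float(np.mean((risk_true[ok] - risk_hat[ok]) ** 2))


def true_risks(truth: SimulationTruth, subjects, l: float, t: float) -> np.ndarray:
    """True conditional risks 1 - S(t)/S(l) for the given subjects."""
    from .simulate import true_conditional_risk

    return np.array([true_conditional_risk(truth, s, l, t) for s in subjects])


def oracle_reference_metrics(truth: SimulationTruth, test_outcomes: pd.DataFrame,
                             G: CensoringDistribution, landmarks, horizons) -> pd.DataFrame:
    """tdAUC/Brier obtained by predicting the *true* conditional risks.

    The performance ceiling of any model on the same evaluation set: MSE is 0
    by construction, but discrimination and calibration stay imperfect
    because individual outcomes remain random.
    """
    rows = []
    for l in landmarks:
        at_risk = test_outcomes.index[test_outcomes["time"] > l]
        if len(at_risk) == 0:
            continue
        T = test_outcomes.loc[at_risk, "time"].to_numpy(float)
        d = test_outcomes.loc[at_risk, "event"].to_numpy(int)
        for t in horizons:
            if t <= l:
                continue
            r = true_risks(truth, at_risk, l, t)
            rows.append(dict(model="oracle", strategy="truth", landmark=l, horizon=t,
                             metric="tdAUC", value=tdauc_ipcw(r, T, d, G, t)))
            rows.append(dict(model="oracle", strategy="truth", landmark=l, horizon=t,
                             metric="Brier", value=brier_ipcw(r, T, d, G, t)))
            rows.append(dict(model="oracle", strategy="truth", landmark=l, horizon=t,
                             metric="MSE", value=0.0))
    return pd.DataFrame(rows)
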