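"""Kaplan-Meier estimation, Cox proportional hazards for a binary
predictor, and the cross-cohort hazard-ratio comparison.

The Cox fit maximises the Breslow-tie partial likelihood for a single
binary covariate by Newton-Raphson (convergence |delta beta| < 1e-8); the
standard error comes from the observed information and the 95 % interval
is exp(beta +/- 1.96 SE). Two independent hazard ratios are compared on
the log scale with a regression-coefficient (Wald z) test; when a fit is
given as a printed interval, its SE is reconstructed as
(ln upper - ln lower) / (2 * 1.96).

Proportionality is checked with a scaled-Schoenfeld-residual trend test
against event time.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import KaplanMeierFitter


@dataclasses.dataclass
class KaplanMeierCurve:
    survival: pd.DataFrame          # index: time, column "S"
    median: float | None            # inf{t : S(t) <= 0.5}; None if not reached


@dataclasses.dataclass
class SurvivalFit:
    beta: float
    se: float
    hazard_ratio: float
    ci: tuple[float, float, float]  # (h_r, -b, +c): interval [h_r - b, h_r + c]
    p: float
    n_iter: int = 0
    flag: str | None = None         # e.g. "monotone_likelihood"

    @property
    def ci_bounds(self) -> tuple[float, float]:
        a, b, c = self.ci
        return a - b, a + c


def kaplan_meier(times, events) -> KaplanMeierCurve:
    """Product-limit survival estimate with the standard median definition."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    surv = kmf.survival_function_.rename(columns={"KM_estimate": "S"})
    med = kmf.median_survival_time_
    return KaplanMeierCurve(survival=surv,
                            median=None if np.isinf(med) else float(med))


def _breslow_terms(times, events, group):
    """Per distinct event time: (d, s1, n0, n1) for the Breslow likelihood."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    z = np.asarray(group).astype(int)
    terms = []
    for tj in np.unique(t[e]):
        at_risk = t >= tj
        dying = e & (t == tj)
        terms.append((int(dying.sum()), int(z[dying].sum()),
                      int((at_risk & (z == 0)).sum()), int((at_risk & (z == 1)).sum())))
    return terms


def cox_binary(times, events, group, tol: float = 1e-8,
               max_iter: int = 100) -> SurvivalFit:
    """Cox proportional-hazards fit for a binary group indicator.

    Requires at least one observed event in each group; otherwise the
    partial likelihood is monotone in beta and no estimate exists (the
    returned fit carries the ``monotone_likelihood`` flag and NaNs).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    z = np.asarray(group).astype(int)
    if set(np.unique(z)) - {0, 1}:
        raise ValueError("group must be binary (0/1)")
    if not e[z == 0].any() or not e[z == 1].any():
        return SurvivalFit(beta=np.nan, se=np.nan, hazard_ratio=np.nan,
                           ci=(np.nan, np.nan, np.nan), p=np.nan,
                           flag="monotone_likelihood")

    terms = _breslow_terms(t, e, z)
    beta = 0.0
    for it in range(1, max_iter + 1):
        score = 0.0
        info = 0.0
        eb = np.exp(beta)
        for d, s1, n0, n1 in terms:
            denom = n0 + n1 * eb
            mean = n1 * eb / denom
            score += s1 - d * mean
            info += d * (n0 * n1 * eb) / denom**2
        step = score / info
        beta += step
        if abs(step) < tol:
            break
    se = 1.0 / np.sqrt(info)
    hr = float(np.exp(beta))
    lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
    p = 2.0 * scipy.stats.norm.sf(abs(beta) / se)
    return SurvivalFit(beta=float(beta), se=float(se), hazard_ratio=hr,
                       ci=(hr, hr - float(lo), float(hi) - hr), p=float(p),
                       n_iter=it)


def _log_scale(fit) -> tuple[float, float]:
    """(beta, SE) from a SurvivalFit or a printed (h_r, lower, upper) triple."""
    if isinstance(fit, SurvivalFit):
        if not np.isfinite(fit.beta) or not np.isfinite(fit.se):
            raise ValueError("fit has no estimate (monotone likelihood?)")
        return fit.beta, fit.se
    hr, lo, hi = fit
    if lo <= 0 or hi <= 0 or hr <= 0:
        raise ValueError("hazard ratio and CI bounds must be positive")
    return float(np.log(hr)), float((np.log(hi) - np.log(lo)) / (2 * 1.96))


def compare_hazard_ratios(fit1, fit2) -> float:
    """Two-sided p for equality of two independent hazard ratios.

    z = (beta_1 - beta_2) / sqrt(SE_1^2 + SE_2^2) on the log scale. Each
    argument is a SurvivalFit or an (h_r, ci_lower, ci_upper) triple as
    printed in a report.
    """
    b1, s1 = _log_scale(fit1)
    b2, s2 = _log_scale(fit2)
    z = (b1 - b2) / np.sqrt(s1**2 + s2**2)
    return float(2.0 * scipy.stats.norm.sf(abs(z)))


@dataclasses.dataclass
class PHDiagnostic:
    correlation: float
    p: float
    n_events: int
    flag: str | None = None


def ph_check(times, events, group) -> PHDiagnostic:
    """Proportional-hazards diagnostic: scaled Schoenfeld residuals are
    correlated against event time (Pearson, two-sided t-test p). A
    significant trend indicates a time-varying hazard ratio."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    z = np.asarray(group).astype(int)
    fit = cox_binary(t, e, z)
    if fit.flag is not None:
        return PHDiagnostic(np.nan, np.nan, int(e.sum()), flag=fit.flag)
    eb = np.exp(fit.beta)
    resid, etimes = [], []
    for tj in np.unique(t[e]):
        at_risk = t >= tj
        n1 = int((at_risk & (z == 1)).sum())
        n0 = int((at_risk & (z == 0)).sum())
        denom = n0 + n1 * eb
        mean = n1 * eb / denom
        var = n0 * n1 * eb / denom**2
        if var <= 0:
            continue
        for zi in z[e & (t == tj)]:
            resid.append((zi - mean) / var)  # scaled residual
            etimes.append(tj)
    if len(resid) < 3 or np.unique(etimes).size < 2 or np.std(resid) == 0:
        return PHDiagnostic(np.nan, np.nan, len(resid), flag="too_few_events")
    r, p = scipy.stats.pearsonr(resid, etimes)
    return PHDiagnostic(correlation=float(r), p=float(p), n_events=len(resid))
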