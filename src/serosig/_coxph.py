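"""Univariate Cox proportional-hazards fitting (Newton, Efron ties).

A single-covariate partial-likelihood fit kept deliberately lean: the
screening stage runs hundreds of fits per cohort and thousands across
simulation seeds. lifelines is used elsewhere for multivariate models
and serves as the independent oracle for this module in the tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class CoxUnivariateFit:
    beta: float
    se: float
    z: float
    p: float
    hr: float
    ci_low: float
    ci_high: float
    n: int
    n_events: int
    converged: bool


class CoxFitError(ValueError):
    pass


def _efron_derivatives(beta: float, x: np.ndarray, tie_first: np.ndarray,
                       tie_last: np.ndarray, event_in_group: list) -> tuple:
    """Log partial likelihood, gradient and information at ``beta``.

    ``x`` is sorted by ascending time; ``tie_first/tie_last`` delimit tied
    time groups that contain at least one event; ``event_in_group`` holds
    the sorted-order indices of the events in each group.
    """
    eta = beta * x
    eta -= eta.max()  # guard overflow; cancels in the ratios
    w = np.exp(eta)
    wx = w * x
    wx2 = wx * x
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1])[::-1]
    S2 = np.cumsum(wx2[::-1])[::-1]

    loglik = 0.0
    grad = 0.0
    info = 0.0
    for g, first in enumerate(tie_first):
        ev = event_in_group[g]
        d = len(ev)
        s0r, s1r, s2r = S0[first], S1[first], S2[first]
        s0t = w[ev].sum()
        s1t = wx[ev].sum()
        s2t = wx2[ev].sum()
        loglik += eta[ev].sum()
        for l in range(d):
            f = l / d
            d0 = s0r - f * s0t
            d1 = s1r - f * s1t
            d2 = s2r - f * s2t
            loglik -= np.log(d0)
            m = d1 / d0
            grad -= m
            info += d2 / d0 - m * m
        grad += x[ev].sum()
    return loglik, grad, info


def fit_cox_univariate(x, time, event, max_iter: int = 60, tol: float = 1e-10) -> CoxUnivariateFit:
    """Newton fit of a one-covariate Cox model with Efron tie handling.

    Raises ``CoxFitError`` for degenerate inputs (constant covariate,
    fewer than two events); returns ``converged=False`` when the partial
    likelihood is monotone (separation-like behaviour).
    """
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if x.shape != time.shape or x.shape != event.shape:
        raise CoxFitError("x, time and event must have equal length")
    if not np.all(np.isfinite(x)):
        raise CoxFitError("covariate contains non-finite values")
    if event.sum() < 2:
        raise CoxFitError("need at least 2 events for a Cox fit")
    if np.ptp(x) == 0:
        raise CoxFitError("constant covariate has no partial-likelihood information")

    order = np.argsort(time, kind="mergesort")
    xs, ts, ds = x[order], time[order], event[order]

    # tied-time groups containing at least one event
    tie_first, tie_last, event_in_group = [], [], []
    i, n = 0, len(ts)
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        ev = [k for k in range(i, j + 1) if ds[k] == 1]
        if ev:
            tie_first.append(i)
            tie_last.append(j)
            event_in_group.append(np.asarray(ev))
        i = j + 1
    tie_first = np.asarray(tie_first)
    tie_last = np.asarray(tie_last)

    beta = 0.0
    converged = False
    info = np.nan
    for _ in range(max_iter):
        _, grad, info = _efron_derivatives(beta, xs, tie_first, tie_last, event_in_group)
        if info <= 0:
            break
        step = grad / info
        if abs(step) > 2.0:
            step = np.sign(step) * 2.0
        beta += step
        if abs(step) < tol:
            converged = True
            break
        if abs(beta) > 20:
            break

    se = float(1.0 / np.sqrt(info)) if info and info > 0 else np.nan
    zval = beta / se if se and np.isfinite(se) else np.nan
    p = float(2.0 * stats.norm.sf(abs(zval))) if np.isfinite(zval) else np.nan
    return CoxUnivariateFit(
        beta=float(beta),
        se=se,
        z=float(zval),
        p=p,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        n=int(n),
        n_events=int(event.sum()),
        converged=converged and abs(beta) <= 20,
    )
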