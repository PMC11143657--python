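"""Independent brute-force oracles used to check the estimators.

Everything here is written as plain per-time loops over the definition of
each quantity, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_curves(times, events):
    """Product-limit and cumulative-incidence values by direct recursion.

    Returns a dict ``time -> (one_minus_km, cif_ae, cif_ce, surv)`` at every
    distinct observation time, computed by looping over the definitions:
    the risk set at t is everyone with observation time >= t, events at a
    time are processed against that risk set, censorings removed afterwards.
    """
    times = list(map(float, times))
    events = list(map(int, events))
    km = 1.0
    surv = 1.0
    cif_ae = 0.0
    cif_ce = 0.0
    out = {}
    for t in sorted(set(times)):
        at_risk = sum(1 for x in times if x >= t)
        d_ae = sum(1 for x, e in zip(times, events) if x == t and e == 1)
        d_ce = sum(1 for x, e in zip(times, events) if x == t and e == 2)
        if at_risk > 0:
            km *= 1.0 - d_ae / at_risk
            cif_ae += surv * d_ae / at_risk
            cif_ce += surv * d_ce / at_risk
            surv *= 1.0 - (d_ae + d_ce) / at_risk
        out[t] = (1.0 - km, cif_ae, cif_ce, surv)
    return out


def breslow_partial_loglik(beta, times, status, group):
    """Breslow partial log-likelihood of a two-group Cox model, by loops."""
    times = list(map(float, times))
    status = list(map(int, status))
    group = list(map(int, group))
    ll = 0.0
    for t in sorted({x for x, s in zip(times, status) if s}):
        d = [i for i, (x, s) in enumerate(zip(times, status)) if x == t and s]
        risk = [i for i, x in enumerate(times) if x >= t]
        denom = sum(math.exp(beta * group[i]) for i in risk)
        for i in d:
            ll += beta * group[i] - math.log(denom)
    return ll


def grid_argmax_cox(times, status, group, lo=-4.0, hi=4.0, step=1e-4):
    """Grid-search maximizer of the Breslow partial likelihood.

    The likelihood is evaluated on a dense beta grid, vectorized over the
    grid but looping over the event-time definition.
    """
    betas = np.arange(lo, hi + step / 2, step)
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    group = np.asarray(group, dtype=int)
    ll = np.zeros_like(betas)
    for t in np.unique(times[status == 1]):
        d = (times == t) & (status == 1)
        risk = times >= t
        n1 = int((risk & (group == 1)).sum())
        n0 = int((risk & (group == 0)).sum())
        s = int((d & (group == 1)).sum())
        ll += s * betas - d.sum() * np.log(n0 + n1 * np.exp(betas))
    return float(betas[np.argmax(ll)]), float(ll.max())
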