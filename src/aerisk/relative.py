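"""Between-arm relative effects: risk ratios, incidence-density ratios,
cause-specific Cox hazard ratios, and bootstrap comparison to gold standards.

The risk ratio (RR) divides arm-wise AE probabilities computed with any of
the absolute-risk estimators at a common evaluation time tau; its gold
standard uses the Aalen-Johansen estimator in each arm.  The gold standard
for hazard-based effects is the cause-specific hazard ratio from a two-group
Cox model; the incidence-density ratio (IDR) is its constant-hazard
competitor.  RRs carry an evaluation time; HRs use the whole follow-up and
carry none.

A RR is *undefined* (``defined=False``, no exception) when either arm-wise
probability is zero, so batch analyses can tabulate exclusions instead of
aborting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import absolute
from .io import ADVERSE_EVENT, COMPETING_EVENT, EXPERIMENTAL, CONTROL, TrialDataset, max_eval_time

MEASURE_RR = "RR"
MEASURE_HR = "HR"
MEASURE_IDR = "IDR"


@dataclass(frozen=True)
class RelativeEffect:
    """A relative-effect point estimate with a log-scale Wald CI.

    ``defined`` is False when the effect cannot be formed (e.g. an arm-wise
    probability of zero); point and bounds are NaN in that case.
    """

    measure: str            # "RR", "HR_AE", "HR_CE", "IDR_AE", "IDR_CE"
    point: float
    lower: float
    upper: float
    level: float
    log_variance: float
    tau: float | None = None
    basis: str | None = None  # absolute-risk estimator behind a RR
    defined: bool = True
    note: str = ""


def _wald_ci(point: float, log_var: float, level: float) -> tuple[float, float]:
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(log_var)
    return float(point * np.exp(-half)), float(point * np.exp(half))


def _undefined(measure: str, level: float, tau=None, basis=None, note="") -> RelativeEffect:
    return RelativeEffect(
        measure=measure, point=float("nan"), lower=float("nan"), upper=float("nan"),
        level=level, log_variance=float("nan"), tau=tau, basis=basis,
        defined=False, note=note,
    )


# ---------------------------------------------------------------------------
# risk ratio
# ---------------------------------------------------------------------------

def risk_ratio_from_probs(
    q_e: float, var_e: float, q_c: float, var_c: float,
    *, level: float = 0.95, tau: float | None = None, basis: str | None = None,
) -> RelativeEffect:
    """RR from arm-wise probabilities with delta-rule log variance.

    ``Var(log RR) = Var(q_E)/q_E^2 + Var(q_C)/q_C^2``; Wald CI on the log
    scale.  Zero probability in either arm yields ``defined=False``.
    """
    if q_e == 0 or q_c == 0:
        return _undefined(MEASURE_RR, level, tau=tau, basis=basis,
                          note="AE probability is 0 in at least one arm")
    point = q_e / q_c
    log_var = var_e / q_e ** 2 + var_c / q_c ** 2
    lo, hi = _wald_ci(point, log_var, level)
    return RelativeEffect(
        measure=MEASURE_RR, point=float(point), lower=lo, upper=hi,
        level=level, log_variance=float(log_var), tau=tau, basis=basis,
    )


def risk_ratio(
    data: TrialDataset, basis: str = absolute.ESTIMATOR_AJE,
    tau: float | None = None, level: float = 0.95,
) -> RelativeEffect:
    """Arm-wise AE-probability ratio (experimental / control) at ``tau``.

    ``tau`` defaults to the pooled maximal evaluation time.
    """
    data.require_two_arms()
    if tau is None:
        tau = max_eval_time(data)
    qe = absolute.estimate(data, EXPERIMENTAL, tau, basis)
    qc = absolute.estimate(data, CONTROL, tau, basis)
    return risk_ratio_from_probs(
        qe.point, qe.variance, qc.point, qc.variance, level=level, tau=tau, basis=basis
    )


# ---------------------------------------------------------------------------
# incidence-density ratio
# ---------------------------------------------------------------------------

def incidence_density_ratio(
    data: TrialDataset, event="AE", tau: float | None = None, level: float = 0.95
) -> RelativeEffect:
    """Ratio of arm-wise incidence densities for the given event type.

    ``Var(log IDR) = 1/D_E + 1/D_C`` from Poisson event counts.
    """
    data.require_two_arms()
    if tau is None:
        tau = max_eval_time(data)
    code = absolute._event_code(event)
    name = f"{MEASURE_IDR}_{'AE' if code == ADVERSE_EVENT else 'CE'}"
    d_e, pt_e = absolute.rate_components(data, EXPERIMENTAL, tau, code)
    d_c, pt_c = absolute.rate_components(data, CONTROL, tau, code)
    if d_e == 0 or d_c == 0:
        return _undefined(name, level, tau=tau, note="no events of this type in at least one arm")
    point = (d_e / pt_e) / (d_c / pt_c)
    log_var = 1.0 / d_e + 1.0 / d_c
    lo, hi = _wald_ci(point, log_var, level)
    return RelativeEffect(
        measure=name, point=float(point), lower=lo, upper=hi,
        level=level, log_variance=float(log_var), tau=tau,
    )


# ---------------------------------------------------------------------------
# cause-specific Cox hazard ratio
# ---------------------------------------------------------------------------

def _cox_tables(data: TrialDataset, code: int):
    """Distinct event times with (d_i, s_i, n1_i, n0_i) for the two-group fit."""
    te_all, ev_e = data.arm_arrays(EXPERIMENTAL)
    tc_all, ev_c = data.arm_arrays(CONTROL)
    ev_times = np.concatenate((te_all[ev_e == code], tc_all[ev_c == code]))
    tgrid = np.unique(ev_times)
    # events in the experimental arm per distinct time
    s = np.bincount(np.searchsorted(tgrid, te_all[ev_e == code]), minlength=len(tgrid))
    d = np.bincount(np.searchsorted(tgrid, ev_times), minlength=len(tgrid))
    sorted_e = np.sort(te_all)
    sorted_c = np.sort(tc_all)
    n1 = len(sorted_e) - np.searchsorted(sorted_e, tgrid, side="left")
    n0 = len(sorted_c) - np.searchsorted(sorted_c, tgrid, side="left")
    return tgrid, d.astype(float), s.astype(float), n1.astype(float), n0.astype(float)


def cox_partial_loglik(beta: float, d, s, n1, n0) -> float:
    """Breslow partial log-likelihood of a two-group proportional-hazards model."""
    return float(np.sum(s * beta - d * np.log(n0 + n1 * np.exp(beta))))


def cox_hr(
    data: TrialDataset, event="AE", level: float = 0.95,
    *, tol: float = 1e-8, max_iter: int = 50,
) -> RelativeEffect:
    """Cause-specific Cox hazard ratio (experimental vs control).

    The other event type and censoring are treated as censored.  Breslow tie
    handling; Newton-Raphson on the partial likelihood.  With all events of
    the type in a single arm the partial likelihood is monotone and the
    effect is returned as ``defined=False`` with a diverging-estimate note.
    """
    data.require_two_arms()
    code = absolute._event_code(event)
    name = f"{MEASURE_HR}_{'AE' if code == ADVERSE_EVENT else 'CE'}"
    tgrid, d, s, n1, n0 = _cox_tables(data, code)
    if len(tgrid) == 0:
        raise ValueError(f"no events of type {event!r} in the dataset")
    if s.sum() == 0 or s.sum() == d.sum():
        return _undefined(name, level, note="diverging estimate: all events in one arm")

    beta = 0.0
    for _ in range(max_iter):
        eb = np.exp(beta)
        p = n1 * eb / (n0 + n1 * eb)
        score = float(np.sum(s - d * p))
        info = float(np.sum(d * p * (1.0 - p)))
        if info <= 0:
            return _undefined(name, level, note="singular information")
        step = score / info
        beta += step
        if abs(step) < tol:
            break
    eb = np.exp(beta)
    p = n1 * eb / (n0 + n1 * eb)
    info = float(np.sum(d * p * (1.0 - p)))
    log_var = 1.0 / info
    point = float(np.exp(beta))
    lo, hi = _wald_ci(point, log_var, level)
    return RelativeEffect(
        measure=name, point=point, lower=lo, upper=hi,
        level=level, log_variance=log_var, tau=None,
    )


# ---------------------------------------------------------------------------
# bootstrap comparison to the gold standard
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoldComparison:
    """Ratio of a comparator effect to its gold standard with a bootstrap CI."""

    measure: str
    basis: str | None
    point: float
    lower: float
    upper: float
    level: float
    n_boot: int
    n_dropped: int


def _effect_pair(data: TrialDataset, basis: str, measure: str, tau: float, level: float):
    if measure == MEASURE_RR:
        gold = risk_ratio(data, absolute.ESTIMATOR_AJE, tau, level)
        comp = gold if basis == absolute.ESTIMATOR_AJE else risk_ratio(data, basis, tau, level)
    elif measure in (MEASURE_HR, MEASURE_IDR):
        # comparator = constant-hazard IDR, gold = Cox cause-specific HR
        gold = cox_hr(data, "AE", level)
        comp = incidence_density_ratio(data, "AE", tau, level)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return comp, gold


def _resample(data: TrialDataset, rng: np.random.Generator) -> TrialDataset:
    arms = {}
    for arm in data.arms:
        times, events = data.arm_arrays(arm)
        idx = rng.integers(0, len(times), size=len(times))
        arms[arm] = (times[idx], events[idx])
    return TrialDataset.from_arrays(arms, trial_id=data.trial_id, ae_id=data.ae_id)


def ratio_to_gold(
    data: TrialDataset, basis: str = absolute.ESTIMATOR_IP, measure: str = MEASURE_RR,
    tau: float | None = None, B: int = 999, seed=None, level: float = 0.95,
) -> GoldComparison:
    """Comparator-to-gold effect ratio with a percentile bootstrap CI.

    Subjects are resampled with replacement within each arm (the two effects
    are computed on the same data, so their dependence is carried into the
    CI by the subject-level bootstrap).  Resamples on which either effect is
    undefined are dropped and counted in ``n_dropped``.
    """
    data.require_two_arms()
    if tau is None:
        tau = max_eval_time(data)
    comp, gold = _effect_pair(data, basis, measure, tau, level)
    if not (comp.defined and gold.defined):
        raise ValueError("comparator and gold-standard effects must be defined on the full data")
    point = comp.point / gold.point

    rng = np.random.default_rng(seed)
    ratios = []
    dropped = 0
    for _ in range(int(B)):
        boot = _resample(data, rng)
        try:
            comp_b, gold_b = _effect_pair(boot, basis, measure, tau, level)
        except ValueError:
            dropped += 1
            continue
        if not (comp_b.defined and gold_b.defined) or gold_b.point == 0:
            dropped += 1
            continue
        ratios.append(comp_b.point / gold_b.point)
    if ratios:
        lo, hi = np.quantile(ratios, [0.5 - level / 2, 0.5 + level / 2])
    else:
        lo = hi = float("nan")
    return GoldComparison(
        measure=measure, basis=basis if measure == MEASURE_RR else None,
        point=float(point), lower=float(lo), upper=float(hi),
        level=level, n_boot=len(ratios), n_dropped=dropped,
    )


def effects_to_frame(effects, trial_id: str = "", ae_id: str = "") -> pd.DataFrame:
    """Tidy table of relative effects (one row per effect)."""
    return pd.DataFrame(
        [
            {
                "trial_id": trial_id, "ae_id": ae_id, "measure": e.measure,
                "basis": e.basis, "tau": e.tau, "point": e.point,
                "lower": e.lower, "upper": e.upper, "level": e.level,
                "defined": e.defined, "note": e.note,
            }
            for e in effects
        ]
    )
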