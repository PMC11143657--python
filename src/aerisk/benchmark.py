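"""Bias quantification: estimators vs the Aalen-Johansen gold standard on
data, and vs closed-form truth on constant-hazards simulations.

A *unit* is one (dataset, arm); every requested estimator is evaluated at the
unit's maximal evaluation time and expressed as a ratio to the reference
(the AJE on real data, the true cumulative incidence in simulations).
Ratios are pooled across units on the log scale — medians and interquartile
ranges by default, geometric means with a Monte-Carlo standard error of the
log-mean alongside — and exponentiated only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .absolute import ESTIMATOR_AJE, ESTIMATORS, estimate
from .categorize import (
    EvidenceCategory,
    FrequencyCategory,
    SwitchTable,
    evidence_category,
    frequency_category,
    switch_table,
)
from .io import TrialDataset, max_eval_time
from .simulate import ScenarioConfig, ScenarioTruth, simulate_trial


@dataclass
class BiasReport:
    """Per-unit estimator ratios and their pooled summary.

    ``per_unit`` has one row per (unit, arm, estimator); ``pooled`` one row
    per estimator with median / IQR / geometric mean / MC standard error of
    the log ratio.  ``reference`` names what the ratios are taken against.
    """

    per_unit: pd.DataFrame
    pooled: pd.DataFrame
    reference: str
    n_excluded: int = 0


_POOL_COLUMNS = ("n_units", "median_ratio", "q25_ratio", "q75_ratio",
                 "geo_mean_ratio", "mean_ratio", "mc_se_log")


def _pool(per_unit: pd.DataFrame) -> pd.DataFrame:
    if per_unit.empty:
        return pd.DataFrame(columns=list(_POOL_COLUMNS)).rename_axis("estimator")
    rows = []
    for est, grp in per_unit.groupby("estimator", sort=False):
        r = grp["ratio"].to_numpy(dtype=float)
        logs = np.log(r)
        rows.append({
            "estimator": est,
            "n_units": len(r),
            "median_ratio": float(np.median(r)),
            "q25_ratio": float(np.quantile(r, 0.25)),
            "q75_ratio": float(np.quantile(r, 0.75)),
            "geo_mean_ratio": float(np.exp(logs.mean())),
            "mean_ratio": float(r.mean()),
            "mc_se_log": float(logs.std(ddof=1) / np.sqrt(len(r))) if len(r) > 1 else 0.0,
        })
    return pd.DataFrame(rows).set_index("estimator")


def bias_vs_gold(
    datasets: Iterable[TrialDataset],
    estimators: Sequence[str] = ESTIMATORS,
    tau: float | None = None,
) -> BiasReport:
    """Ratio of each estimator to the AJE at the maximal evaluation time.

    Units with a zero AJE are excluded and counted; so are (unit, estimator)
    pairs with a zero estimate (their log-ratio is undefined).
    """
    rows = []
    excluded = 0
    for i, ds in enumerate(datasets):
        tau_d = max_eval_time(ds) if tau is None else tau
        unit = ds.trial_id or f"dataset{i}"
        for arm in ds.arms:
            gold = estimate(ds, arm, tau_d, ESTIMATOR_AJE)
            if gold.point == 0:
                excluded += 1
                continue
            for name in estimators:
                e = estimate(ds, arm, tau_d, name)
                if e.point == 0:
                    excluded += 1
                    continue
                rows.append({
                    "unit": unit, "arm": arm, "estimator": name, "tau": tau_d,
                    "estimate": e.point, "reference": gold.point,
                    "ratio": e.point / gold.point,
                })
    per_unit = pd.DataFrame(rows, columns=["unit", "arm", "estimator", "tau",
                                           "estimate", "reference", "ratio"])
    return BiasReport(per_unit, _pool(per_unit), reference="AJE", n_excluded=excluded)


def run_scenarios(
    configs: Sequence[ScenarioConfig],
    reps: int,
    seed=None,
    estimators: Sequence[str] = ESTIMATORS,
    tau: float | None = None,
) -> BiasReport:
    """Simulate each scenario ``reps`` times and ratio every estimator to truth.

    Each replicate uses an independent child seed spawned from ``seed``, so a
    fixed seed reproduces the full report.  Per-replicate estimation failures
    are excluded and counted, not fatal.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(configs) * reps)
    rows = []
    excluded = 0
    k = 0
    for ci, cfg in enumerate(configs):
        truth = ScenarioTruth.from_config(cfg)
        for rep in range(reps):
            ds = simulate_trial(cfg, seed=children[k])
            k += 1
            tau_r = max_eval_time(ds) if tau is None else tau
            unit = f"scenario{ci}:rep{rep}"
            for arm in ds.arms:
                ref = float(truth.cif_ae(tau_r, arm))
                if ref == 0:
                    excluded += 1
                    continue
                for name in estimators:
                    try:
                        e = estimate(ds, arm, tau_r, name)
                    except ValueError:
                        excluded += 1
                        continue
                    if e.point == 0:
                        excluded += 1
                        continue
                    rows.append({
                        "unit": unit, "arm": arm, "estimator": name, "tau": tau_r,
                        "estimate": e.point, "reference": ref, "ratio": e.point / ref,
                    })
    per_unit = pd.DataFrame(rows, columns=["unit", "arm", "estimator", "tau",
                                           "estimate", "reference", "ratio"])
    return BiasReport(per_unit, _pool(per_unit), reference="truth", n_excluded=excluded)


def category_impact(
    gold: Sequence,
    comparators: Mapping[str, Sequence],
    kind: str = "frequency",
) -> dict[str, SwitchTable]:
    """Switch tables of gold vs each comparator, by frequency or evidence class.

    ``kind='frequency'``: inputs are AE probabilities (or objects with a
    ``point`` attribute).  ``kind='evidence'``: inputs are relative effects;
    undefined effects become unclassifiable and are dropped pairwise.
    """
    def freq(x):
        p = getattr(x, "point", x)
        return None if p is None or not np.isfinite(p) else frequency_category(p)

    def evid(x):
        if x is None or not getattr(x, "defined", True):
            return None
        return evidence_category(x)

    to_cat = {"frequency": freq, "evidence": evid}.get(kind)
    if to_cat is None:
        raise ValueError("kind must be 'frequency' or 'evidence'")
    gold_cats = [to_cat(g) for g in gold]
    return {name: switch_table(gold_cats, [to_cat(c) for c in comp])
            for name, comp in comparators.items()}
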