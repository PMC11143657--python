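"""Between-arm relative effects on a simulated two-arm trial.

The experimental arm has twice the control AE hazard (0.2 vs 0.1 per year),
the same competing-event hazard, and random censoring.  The cause-specific
Cox hazard ratio and the incidence-density ratio both target the hazard
ratio 2; the risk ratio based on arm-wise Aalen-Johansen estimates targets
the ratio of true cumulative incidences at the evaluation time.
"""

from aerisk import cox_hr, incidence_density_ratio, max_eval_time, ratio_to_gold, risk_ratio, simulate_trial
from aerisk.simulate import ScenarioConfig, ScenarioTruth

cfg = ScenarioConfig(n_per_arm=2000, alpha_E=0.2, beta_E=0.3,
                     alpha_C=0.1, beta_C=0.3, gamma=0.1, seed=42)
data = simulate_trial(cfg)
truth = ScenarioTruth.from_config(cfg)
tau = max_eval_time(data)

hr = cox_hr(data, "AE")
idr = incidence_density_ratio(data, "AE", tau)
rr = risk_ratio(data, "AJE", tau)
print(f"true AE hazard ratio      : {truth.hazard_ratio_ae:.3f}")
print(f"Cox cause-specific HR (AE): {hr.point:.3f}  [{hr.lower:.3f}, {hr.upper:.3f}]")
print(f"incidence-density ratio   : {idr.point:.3f}  [{idr.lower:.3f}, {idr.upper:.3f}]")
print(f"true RR at tau={tau:.1f}     : {truth.risk_ratio(tau):.3f}")
print(f"AJE-based risk ratio      : {rr.point:.3f}  [{rr.lower:.3f}, {rr.upper:.3f}]")

cmp_ = ratio_to_gold(data, basis="IP", measure="RR", tau=tau, B=199, seed=1)
print(f"RR(IP) / RR(AJE)          : {cmp_.point:.3f}  "
      f"[{cmp_.lower:.3f}, {cmp_.upper:.3f}]  ({cmp_.n_dropped} resamples dropped)")
print("A ratio near 1 means the incidence-proportion RR tracks the gold standard")
print("on this dataset even though each arm-wise IP underestimates the risk.")
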