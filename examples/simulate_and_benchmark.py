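"""Quantify estimator bias against analytic truth on simulated trials.

A constant-hazards scenario with a competing-event hazard twice the AE
hazard and moderate random censoring is simulated repeatedly; every
estimator is read off at the largest observation time and divided by the
closed-form true cumulative incidence there.  Ratios above 1 mean
overestimation.
"""

from aerisk import run_scenarios
from aerisk.simulate import ScenarioConfig

scenarios = [
    ScenarioConfig(n_per_arm=500, alpha_E=0.15, beta_E=0.30, gamma=0.20),  # CEs + censoring
    ScenarioConfig(n_per_arm=500, alpha_E=0.15, beta_E=0.0, gamma=0.20),   # no CEs
]
report = run_scenarios(scenarios, reps=10, seed=7)

for i, _ in enumerate(scenarios):
    sub = report.per_unit[report.per_unit["unit"].str.startswith(f"scenario{i}")]
    pooled = sub.groupby("estimator")["ratio"].median().round(3)
    print(f"scenario {i} (beta_E={scenarios[i].beta_E}): median ratio to truth")
    print(pooled.to_string(), "\n")

print("With competing events present, 1-KM overshoots the true AE probability")
print("while IP undershoots (censoring); the CE-aware density transform and the")
print("Aalen-Johansen estimator stay near 1. Without CEs, 1-KM and AJE coincide.")
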