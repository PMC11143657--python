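"""The five absolute-risk estimators on a four-subject dataset.

One arm observes an AE at t=1, a competing event at t=2, a censoring at t=3
and an AE at t=4.  Reading all estimators off at tau=4 shows how differently
they treat censoring and competing events on the same data.
"""

import aerisk as ar

data = ar.TrialDataset.from_arrays(
    {"experimental": ([1.0, 2.0, 3.0, 4.0], [ar.ADVERSE_EVENT, ar.COMPETING_EVENT,
                                             ar.CENSORED, ar.ADVERSE_EVENT])},
    trial_id="toy4", ae_id="AE1",
)
tau = ar.max_eval_time(data)
print(f"evaluation time tau = {tau}")
for name in ar.ESTIMATORS:
    est = ar.estimate(data, "experimental", tau, name)
    print(f"  {name:5s}  P(AE by tau) = {est.point:.4f}   (variance {est.variance:.4f})")

_, cif_ae, cif_ce, surv = ar.aj_components(data, "experimental")
print(f"conservation at the last event time: "
      f"{cif_ae[-1]:.2f} + {cif_ce[-1]:.2f} + {surv[-1]:.2f} = "
      f"{cif_ae[-1] + cif_ce[-1] + surv[-1]:.2f}")
print("1-KM reaches 1.0 because it treats the competing event as censoring;")
print("the Aalen-Johansen estimate 0.75 is the unbiased cumulative incidence.")
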