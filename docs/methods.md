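# Methods

## Data model

All estimators consume time-to-first-event data: per subject, the time from
randomization to the first of (AE of interest, competing event, censoring)
and an event code 0/1/2. Times are strictly positive (an AE at the moment of
randomization is invalid) and unit-agnostic; the simulator uses years.
Recurrent AEs are out of scope — one dataset describes one AE type, first
occurrence only. A load-time option recodes all non-death competing events
to censorings (the "death only as CE" sensitivity definition); this needs a
`ce_subtype` column.

The default evaluation time τ is the *pooled maximal evaluation time* — the
latest observation in the dataset across arms. Pooling (rather than per-arm
maxima) keeps the two arms' probabilities comparable at a common τ; arm-wise
variants are available by filtering first. Reading a curve beyond its last
observation carries the last value forward and flags the estimate as
extrapolated.

## Absolute-risk estimators

Let the distinct observation times be t₁ < t₂ < …, with dᴬᴱᵢ, dᶜᴱᵢ events
and cᵢ censorings at tᵢ, and nᵢ the risk set (everyone with time ≥ tᵢ).
Ties: all events at a time are evaluated against that risk set; censorings
at the same time leave afterwards; AE and CE ties share the risk set, which
is decremented after both.

- **Incidence proportion** `d_AE(τ)/n`, binomial variance `p(1−p)/n`. It
  estimates the probability that an AE occurs by τ *and is observed* — it
  handles CEs correctly but ignores censoring.
- **Incidence density** `ID = d(τ) / Σᵢ min(tᵢ, τ)` (events per person-time)
  for either event type. The probability transform `1 − exp(−ID_AE·τ)` is a
  constant-hazard model ignoring CEs; the CE-aware transform is
  `a/(a+b)·(1 − exp(−(a+b)τ))` with `a = ID_AE`, `b = ID_CE` (defined as 0
  when `a+b = 0`). Variances are by the delta method treating event counts
  as independent Poisson — standard for rate estimators and consistent with
  the constant-hazard model itself.
- **One minus Kaplan-Meier** on time to AE, with CEs treated as censorings;
  Greenwood variance. At a time where the risk set is exhausted by AE events
  the Greenwood sum is degenerate and the variance is reported as 0 (the
  point estimate is exactly 1 there).
- **Aalen-Johansen** `ĈIF_e(τ) = Σ_{tᵢ≤τ} Ŝ(tᵢ−)·dₑᵢ/nᵢ` with Ŝ the
  all-cause product-limit survival. The pointwise variance is the Aalen-type
  counting-process estimator
  `Σᵢ [(F(t)−F(tᵢ))² aᵢ + Ŝ(tᵢ−)²((nᵢ−dₑᵢ)/nᵢ)dₑᵢ/nᵢ² − 2(F(t)−F(tᵢ))Ŝ(tᵢ−)dₑᵢ/nᵢ²]`,
  `aᵢ = dᵢ/(nᵢ(nᵢ−dᵢ))` (0 when the risk set is exhausted), rearranged into
  cumulative sums so whole curves cost O(k). It reduces exactly to Greenwood
  without CEs and is cross-validated against a subject-level bootstrap in
  the tests.

Structural identities (all tested, at machine precision): CIF_AE + CIF_CE +
S = 1 at every event time; AJE equals one minus Kaplan-Meier when no CEs
exist; incidence proportion equals the AJE at the maximal time when nothing
is censored; one minus Kaplan-Meier dominates the AJE pointwise, and the
AJE at the maximal time dominates the incidence proportion (each AE's AJE
weight Ŝ(tᵢ−)/nᵢ is at least 1/n).

When probability confidence intervals are requested they are Wald intervals
on the complementary log-log scale, clipped to [0,1], which respects the
range of a probability.

## Relative effects

- **Risk ratio** `RR = q̂_E/q̂_C` at a common τ with any basis estimator;
  `Var(log RR) = Var(q̂_E)/q̂_E² + Var(q̂_C)/q̂_C²` (delta rule) and a Wald CI
  on the log scale. A zero probability in either arm makes the effect
  *undefined* rather than raising, so batch runs can count exclusions.
- **Incidence-density ratio** with `Var(log IDR) = 1/D_E + 1/D_C` (Poisson).
- **Cause-specific Cox HR** from a two-group proportional-hazards fit in
  which the other event type and censorings are censored. Breslow tie
  handling (adequate for a two-group fit with modest ties, and exactly
  reproducible); Newton-Raphson on the partial likelihood, tolerance 1e−8 on
  the step, at most 50 iterations; Wald CI from the observed information.
  All events of the type in one arm means a monotone likelihood: the effect
  is returned undefined with a diverging-estimate note. HRs use the entire
  follow-up and carry no τ; RRs always carry one.
- **Ratio to the gold standard**: comparator and gold effects are computed
  on the same subjects, so their dependence is captured by resampling whole
  subjects with replacement within each arm; the percentile interval of the
  ratio over B resamples (default 999) is reported, along with the count of
  resamples dropped because an effect was undefined. Identical seeds give
  identical intervals.

## Categorization

Frequency classes apply the percent thresholds <0.01%, <0.1%, <1%, <10%,
≥10% (strict "<" at each upper edge, "≥" closing the top class). Evidence
classes: *no effect* when 1 lies in the CI; otherwise, for an effect above
1, the CI's lower bound ≤1.11 is *minor*, ≤1.33 *considerable*, >1.33
*major*, and symmetrically below 1 by the upper bound against 0.9 and 0.75.
The published interval notation overlaps at the edges; this package resolves
a bound lying exactly on an edge toward the **less severe** class, and all
eight constants live in one table in `categorize.py`. Undefined effects are
excluded from switch tables and surfaced in a separate dropped count.

## Simulator

Per subject the first-event time is exponential with the total rate α+β and
the type is AE with probability α/(α+β) — equivalent to latent competing
exponentials but one draw cheaper. Censoring is the minimum of an
exponential time (hazard γ) and the administrative horizon minus a uniform
entry offset on [0, entry_window]; the staggered entry is what generates
varying follow-up, and width 0 recovers common follow-up. Hazards are per
year. Closed forms: `CIF_AE(t) = α/(α+β)(1−e^{−(α+β)t})`, the KM estimand
`1−e^{−αt}`, their ratio drifting to `(α+β)/α`, the true RR as a ratio of
CIFs, and the true HR `α_E/α_C`. `expm1` is used so the identities hold at
very small hazards and times.

What the generator does **not** emulate: non-constant hazards, informative
censoring, recurrent events, covariate-dependent risks. Green tests
therefore certify correctness of the estimators and the direction and
magnitude of their structural biases under the constant-hazards model — not
estimator behaviour under hazard shapes the model excludes (that gap is
precisely the constant-hazard assumption quantified by the ID/ID-CE rows of
the benchmark reports).

## Benchmarking

Each (dataset, arm, estimator) contributes a ratio — to the AJE on data, to
the closed-form truth on simulations — at the unit's maximal evaluation
time (a `tau` override allows sensitivity runs at shorter times). Zero
references or zero estimates are excluded and counted, since ratios are
pooled on the log scale: medians and IQRs by default (robust across
heterogeneous units), geometric means with the Monte-Carlo standard error of
the log mean alongside, exponentiated only at report time. Scenario runs
spawn one child seed per replicate from the master seed, so reports are
bit-reproducible.

Problem sizes in the shipped tests and in `scripts/acceptance.py` (20
replicates at n = 5000/arm for effect recovery; 20 simulated trials at
n = 500/arm for the gold-standard benchmark; n = 10000 for distributional
checks) were chosen so each check's Monte-Carlo error is comfortably below
the tolerance it asserts while the whole suite stays quick.

## Known limitations

- Variance formulas for the density transforms rely on the Poisson/constant
  hazard model being roughly right; under strongly non-constant hazards the
  point estimates are biased anyway, which is the phenomenon under study.
- The far tail of a Kaplan-Meier curve (risk sets of 1–3 subjects) is
  erratic; estimates read off at the very largest observation time inherit
  that noise, which is visible in the headline inflation-factor simulation.
- No covariate adjustment, stratification, or subdistribution-hazard
  (Fine-Gray) models; the comparisons here are two-group and cause-specific.
- Meta-analytic pooling across heterogeneous real trials (beyond the
  median/IQR summaries of the benchmark reports) is not implemented.
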