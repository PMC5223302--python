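# Methods

`triarm` simulates and reanalyzes a three-arm cluster-randomized
hand-hygiene trial in office workplaces: 21 clusters grouped into 7
triplets by a contagion-risk score, one cluster per triplet randomized to
each of a control arm, a soap-and-water wash arm, and an alcohol-rub arm.
Participants filed weekly self-reports of respiratory (RTI) and
gastrointestinal (GTI) symptoms and of recognized exposure to persons with
homologous symptoms.  The analysis endpoint is the *week with reported
symptoms* — a report week containing at least one symptomatic day — and the
central scientific move is conditioning the intervention contrast on the
self-reported exposure, so that only unrecognized exposure remains
unadjusted.

## The analysis model

For reported person-week `r` with symptom indicator `y_r`:

```
y_r ~ Bernoulli(p_r)
log p_r = x_r' beta + u_person(r) + v_cluster(r)
u_i ~ N(0, sigma_person^2),   v_j ~ N(0, sigma_cluster^2)
```

Fixed effects: intervention arm (control reference), reported homologous
exposure at one of two timings (same week, or the immediately preceding
week), optionally the arm-by-exposure interaction, calendar month
(seasonality), and optionally the randomization triplet.  The log link
makes `exp(beta)` a risk ratio; its price is the support constraint
`p_r < 1`, which the sampler enforces by rejecting any state with a
non-negative linear predictor at an observed covariate pattern.

Longitudinal dependence within a reporter is carried entirely by the person
intercept (exchangeable weeks given `u_i`); no autoregressive structure is
fitted.  Rows whose previous week was unreported have an undefined lagged
exposure and are excluded from following-week fits only.

Priors are proper but vague: Normal(0, 10^2) on all fixed effects (log
scale) and half-normal(scale 2) on both random-effect SDs.  Doubling the
fixed-effect prior SD moves the reported contrasts by well under half a
posterior SD (checked in the test suite), and adding triplet indicators is
similarly negligible, so default fits omit the triplet term and expose
`include_triplet` for sensitivity runs.

## Descriptive quantities

- **ReR** (exposure-conditioned relative risk) at a timing is
  `P(symptoms | homologous exposure) / P(symptoms | no exposure)`.  The
  ratio of conditional symptom proportions is the definition that
  reproduces the published stratified tables; the package computes it from
  exact integer counts.
- **Descriptive RRa** is `ReR(arm) / ReR(control)`; undefined ratios
  (empty or zero-event strata) are flagged rather than raised.
- Interval estimates for raw proportions are central 95% Jeffreys
  (Beta(1/2,1/2) posterior) intervals; counts are stored exactly and
  proportions recompute from them bit-identically.
- Display rounding is half-even at 3 decimal places; full precision is kept
  internally.

## Posterior computation

Sampling is adaptive Metropolis-within-Gibbs over `(beta, u, v,
sigma_person, sigma_cluster)`, written against binomial cells: rows with
identical (person, covariate pattern) are aggregated, which leaves the
posterior unchanged and shrinks the likelihood evaluation several-fold.
Moves per iteration:

1. per-coordinate random walks on `beta` (each touches only the rows where
   its design column is nonzero);
2. a joint `beta` move using a proposal covariance learned during burn-in;
3. parallel single-site updates of all person, then all cluster intercepts
   (conditionally independent given the rest);
4. slice sampling of `log sigma` in the centered conditional;
5. a non-centered scale move — slice sampling `log sigma` with the
   standardized intercepts held fixed (`u -> c*u` as `sigma -> c*sigma`) —
   which is what traverses the funnel between the RE scale and its
   realizations;
6. a likelihood-invariant translation trading the fixed intercept against
   the random-intercept means.

Proposal scales adapt only during burn-in (the first half of the chain).
Kept draws are thinned to at most 1,000 per chain by default (hard cap
10,000).  Convergence is assessed with split R-hat and bulk ESS (arviz) on
all fixed effects and both SDs; a fit raises, naming the offending
parameters, when any R-hat exceeds 1.05 or any ESS falls below 200.
`fit_mcmc_retry` wraps this with an escalating iteration schedule.
Identical seeds give identical draws.

Numerical details: the per-row `log(1 - exp(eta))` terms are maintained
incrementally and refreshed every 2,000 iterations against float drift;
random-effect vectors are initialized with small jitter so the centered
sigma conditional is proper from the first iteration, and `log sigma` is
floored at -18 to stay representable.

## Predictive margins

The margin for (arm, exposure status) is a *new-individual* standardized
prevalence: for each posterior draw, every row of the standardization
population (all reported person-weeks pooled across arms, months as
observed) is set to the target arm and exposure, fresh `u, v ~ N(0,
sigma^2)` are drawn per row, and `exp(eta)` is averaged over rows.  Pooling
the population makes arm contrasts differ only through coefficients, and
the fresh-RE draws are shared across the table's cells within a posterior
draw, so risk ratios are ratios of paired samples.  Values `exp(eta) >= 1`
met during this integration are truncated to `1 - 1e-9`; the truncation
rate is reported, warned about above 1%, and escalated to an error in
strict mode.  Summaries are posterior medians and central 95% intervals
(medians are invariant under the ratio transform); `P(RRa < 1)` is the
fraction of paired ratio draws below 1.

When every arm-by-exposure interaction's central 95% credible interval
contains 0 in a following-week fit, the model is refit without the
interaction and a single per-arm risk ratio is written to both exposure
strata ("a single estimate for the entire arm").  With shared RE draws and
no interaction this equality is exact by construction.

## The synthetic cohort

The generator mirrors the analysis model: weekly risk is log-linear in arm,
same-week exposure, previous-week exposure, arm-by-exposure interaction,
and calendar month, with person and cluster intercepts shared between RTI
and GTI (the minimal shared-frailty structure that lets both endpoints be
tested on one cohort) and independent Bernoulli draws given them.  Exposure
is a marked Bernoulli process per reported week — site marks (only work /
only elsewhere / both) are carried but never modelled — and exposure is
generated causally prior to the same-week symptom draw, a direction the
data themselves cannot identify.  Adherence is a per-week reporting
probability (default 0.85) plus a geometric dropout time (default hazard
0.004/week, mean ~250 weeks, well past follow-up); unreported weeks carry
no symptom or exposure values, and week 1 has no lagged exposure by
definition.  Week indices map to calendar months through the Monday of
each week, anchored at the first Monday of a configurable start month
(default January 2009).

Default calibration (the emulated study conditions): 21 clusters x 37
reporters x 70 weeks; control weekly prevalence about 0.126 (RTI) and
0.027 (GTI); exposure-week proportions about 0.28 (RTI) and 0.066 (GTI)
with arm-specific rates as published; same-week exposure risk ratios 4.8
(RTI) and 14.5 (GTI) with weaker lagged effects (1.35 / 2.0); soap-arm
effects 0.68 (RTI) and 0.59 (GTI) on unexposed weeks with positive
interactions that cancel most of the protection in exposed weeks;
alcohol-rub effects near 1; cosine month effects peaking in January.

The random-intercept SDs default to 0.10 (person) and 0.04 (cluster).
This is deliberately modest: parameters are validated at construction by
maximizing the linear predictor over all covariate patterns with both
random effects at +/-4 SD and requiring `exp(eta) < 1`.  With a GTI
exposed-stratum risk above 0.2, that support condition caps
`4(sigma_p + sigma_c)` at roughly 0.6 — a structural property of
log-binomial models, not a tuning choice.  Consequently the synthetic
cohort under-represents the person-level heterogeneity real diary data
would show; passing tests demonstrate correctness of the machinery under
the model's own assumptions, not robustness to overdispersion beyond them.
Other real-data features the generator does not emulate: contact-network
transmission dynamics, the 2009 pandemic period shift, within-week
symptom-day dependence beyond a single run, and informative (outcome-
dependent) dropout.

## Reduced presets and problem sizes

Replicate studies run at reduced sizes chosen to keep full runs fast while
preserving the design structure:

- *Parameter recovery*: 7 triplets, 40 weeks, 50 reporters/cluster
  (~36,000 person-weeks), seasonality, lagged effects and interactions off
  so the generating exposure and arm effects are exactly the fitted
  coefficients; 20 replicates, 16,000 iterations x 2 chains each.
- *Null calibration*: the same 21-cluster design at 12 weeks x 8
  reporters/cluster, no arm effects, equal exposure rates; 60 replicates.
  P(RRa < 1) for the soap arm is checked for approximate uniformity
  (Kolmogorov-Smirnov).  Keeping all 7 triplets matters here: with only 3
  clusters per arm the arm contrast is dominated by cluster-level
  uncertainty and the posterior probabilities concentrate toward 1/2.
- *Structural report*: the small pipeline preset (3 triplets, 20 weeks, 30
  persons/cluster) with the default calibration coefficients, both
  outcomes and both timings.

## Known limitations

- The sampler is a random-walk scheme; for much larger covariate blocks a
  gradient-based sampler would mix better per iteration.
- The support cap ties admissible heterogeneity to the largest fitted
  risk; datasets with high exposed-stratum risks force small RE scales.
- Descriptive Jeffreys intervals ignore clustering; they summarize raw
  proportions only, while inference belongs to the hierarchical model.
- Margins integrate random effects by Monte Carlo per draw; with very few
  standardization rows the per-draw integration noise becomes visible in
  the margin intervals (paired ratios are largely immune).
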