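# Methods

## Setting

A risk prediction model supplies, for each subject, a linear predictor
`lp` and an absolute risk `r = 1 − S0(t_h)^exp(lp)` at a horizon `t_h`.
The model is to be validated in a nested case–control (NCC) subsample of
a fully enumerated cohort: all cases (subjects with the event inside
follow-up) plus, for each case, `m` controls drawn uniformly without
replacement from the case's *risk set* — the subjects whose observed time
is ≥ the case's event time, restricted to exact matches on any
categorical matching variables, excluding the case itself. Future cases
are eligible as controls before their own event; one subject can be
drawn for several cases. After sampling, one record is kept per subject
(the case record when the subject is ever a case, otherwise one
uniformly chosen control record).

Because cases are over-represented and control selection favours long
follow-up (and matched covariate patterns), metrics computed naively on
the NCC sample estimate properties of the sample, not the cohort.
Inverse-probability-of-sampling weights restore the cohort as the
estimand.

## Sampling probabilities and weights

**Cases.** All cases share `p_j = n_sampled_cases / n_cohort_cases`
(= 1 in a typical NCC).

**Controls, closed form ("km").** Eligibility events are independent
across risk sets under incidence density sampling, so

    p_i = 1 − ∏_j (1 − m / (n_j(t_j) − 1)) ,

the product over the cases for which subject *i* was eligible under the
matched eligibility rule; `n_j(t_j) − 1` is the size of case *j*'s risk
set. Factors are clamped at zero when `m` reaches the risk-set size.
When only a fraction of cases was sampled, the product runs over the
sampled cases only, since only their risk sets triggered sampling. The
implementation's sampler and this formula share one eligibility rule
(`time ≥ t_j`, exact categorical matching, case excluded); a Monte-Carlo
test verifies that empirical inclusion frequencies over thousands of
independent draws match the formula.

**Controls, model-based ("glm", "gam").** A logistic regression of the
sampled-as-control indicator on censoring time (plus matching-variable
dummies), fitted to all non-cases of the cohort; the GAM variant replaces
the linear time term with a penalized B-spline (statsmodels `GLMGam`,
5 df cubic spline). Fitted probabilities are clipped to `[1e−6, 1]`
before inversion. The spline variant tracks the closed-form weights
closely; the logit-linear variant is a cruder approximation of the
mechanically concave inclusion curve and can shift absolute-risk-scale
metrics (O/E, net benefit) by a few percent on simulated data — visible
at replicate-mean precision though well within single-replicate noise.

**Weights.** `w_k = 1/p_k`. Control weights are rescaled by
`n_c / Σ_controls w` so their sum equals the cohort's control count
exactly; case weights are never rescaled. Control weights are ≥ 1 before
rescaling. Rescaling can be disabled (relevant mainly for model-based
weights, whose raw sums are already close to `n_c`); winsorization of raw
control weights is available but off by default.

## Orphan-control replacement

Deduplication can leave a matched set with no control (its control was
claimed as a case, or kept its record in another set). Such sets are
offered a replacement control drawn from the case's matched risk set
among subjects not yet in the sample. A replacement is accepted only if
it moves the sample's raw inverse-probability weight sum **closer to the
cohort size**. The guard matters: a subject leaves the control pool only
when claimed as a case, so unconditional replacement adds
inverse-probability mass the closed-form probabilities do not account
for (replacements are extra draws); measured on simulated cohorts it
inflates the raw weight sum by ~8% and biases weighted metrics under
risk-correlated matching, while the guarded rule keeps replicate-mean
weighted metrics on the full-cohort values. Unconditional replacement is
available via `balance_weight_sum=False`.

## Weighted metrics

**Weighted Kaplan–Meier.** Product-limit estimate with weight masses in
place of counts: at each event time, the summed weight of events over
the summed weight at risk. Subjects censored at an event time are at
risk at that time. If the at-risk mass vanishes the estimate is carried
forward with a warning. Unit weights reproduce the classical estimator
to machine precision.

**C-index.** Usable pairs are orderable pairs: the *anchor* is the
member with the earlier event; the comparator survived longer (or was
censored exactly at the anchor's event time). Risk ties contribute 1/2
(Harrell convention); event-time ties between two events are not usable.
The weighted form divides weighted concordant by weighted usable pairs.
Two pair-weightings are provided: the **pair-product** `w_k · w_j`
(default) and the **anchor-only** `w_k`. The product form is the
default because both members of a pair are sampled with bias, so both
must be corrected: in simulation (cohort n = 800, 101 cases, m = 1, 200
NCC replicates) the anchor form shows a systematic bias of −0.05 while
the product form is unbiased to Monte-Carlo precision (−0.0005). With
unit weights both reduce to the classical C-index.

**Threshold metrics.** High risk means `r > p_t` (strict). For binary
outcomes, TP/FP/TN/FN are weighted indicator sums and SE, SP, PPV, NPV
the usual ratios — with the consequence that a common case weight
cancels in SE, so in a typical NCC the weighted and naive sensitivity
coincide exactly. For survival outcomes, each stratum (above/below
threshold) gets a weighted KM survival at the horizon; TP = (1 −
S_high)·W_high etc., while the positive/negative masses come from the
*overall* weighted KM — stratum-level and pooled KM estimates differ
slightly, and pooling avoids adding incompatible pieces. With no
censoring before the horizon the survival metrics reduce exactly to the
binary ones on the event-by-horizon indicator.

**Calibration.** O/E = weighted KM cumulative incidence at the horizon
divided by the weighted mean predicted risk (1 = perfect mean
calibration, > 1 = underestimation). The calibration slope is the
coefficient of `lp` in a weighted Cox model (survival) or weighted
logistic regression (binary); 1 is ideal, < 1 indicates overfitting.
Grouped calibration cuts subjects at unweighted risk quantiles (weighted
quantiles behind a flag) and reports weighted mean predicted risk,
weighted KM observed incidence and weight mass per group.

**Decision curves.** `NB(p_t) = TP/n − FP/n · p_t/(1 − p_t)` with the
weighted TP/FP of the chosen mode and `n = Σw`. The treat-all curve uses
the same weights with everyone classified positive; treat-none is 0. A
relative harm `h` (missing an event is `h` times worse than an
unnecessary intervention) maps to the threshold `1/(h+1)`.

All ratio-type weighted metrics are invariant to multiplying every
weight by a positive constant, and reduce to their classical
counterparts under unit weights (exactly, or to 1e−12).

## Resampling

The NCC design is stratified, so the bootstrap resamples whole matched
sets with replacement (original set count per replicate) and
cross-validation assigns whole sets to folds (sizes within one set).
Subjects carry their original weights into replicates; weights are not
re-estimated per replicate (a `weight_fn` hook allows it) — reuse is the
cheaper choice and replicate-level weight re-estimation changed nothing
in our simulations at the scales tested. Intervals are percentile
bootstrap; in simulation the 95% interval of the weighted C-index covers
the full-cohort value at or slightly above the nominal rate — the set
bootstrap also resamples cases, which repeated NCC draws from a fixed
cohort hold fixed, so the intervals are conservative for that target.

## Synthetic cohorts

Event times follow a Weibull (default exponential) proportional-hazards
model inverted analytically, so closed-form incidences serve as test
oracles. Defaults emulate a rare-outcome validation cohort: n = 3,000,
three covariates (binary "sex", standard-normal clinical and genetic
scores with log hazard ratios 0.5/0.3/0.4), baseline rate 0.0035/year,
horizon 10 years, administrative end 15 years — ~5% cumulative incidence
at the horizon. Censoring is exponential with per-group rates
(default 0.09/year for sex = 0 vs 0.03 for sex = 1), which distorts the
covariate mix of early leavers and hence of sampled controls — the
mechanism the weights must undo. A configurable miscalibration
(`lp_scale`, `risk_multiplier`) turns the stored model into a known-bad
one so calibration metrics have a known target (e.g. halved risks give
O/E ≈ 2).

What the generator does *not* emulate: competing risks, left truncation,
time-varying covariates or effects, non-proportional hazards,
measurement error in predictors, and real-world weight heterogeneity
beyond the censoring mechanism. Passing tests therefore demonstrate
correctness of the sampling/weighting machinery under a well-specified
PH world, not robustness to those violations.

## Experiment module

`run_experiment` simulates one cohort, draws R NCC replicates per design
— unmatched; matched on a 3-level administrative variable independent of
predictions; matched on 6 quantile bins of the non-genetic part of the
linear predictor (prediction-correlated) — estimates weights by each
requested scheme, and tabulates weighted and naive metrics against the
full-cohort reference. Per-replicate RNG streams derive from the master
seed via `SeedSequence([seed, design, replicate])`, so the pipeline is
deterministic and parallel-safe. Default scale (R = 50, n = 3,000,
m = 1, threshold 5%, net-benefit grid 2–8%) runs in about a minute on one
CPU and reproduces the qualitative pattern: weighted replicate means sit
inside the full-cohort estimate's own bootstrap 95% band; naive O/E, PPV
and net benefit sit far outside it; the naive C-index is biased low,
worst under risk-correlated matching.

## Numerical and design choices

- Eligibility uses `time ≥ t_j`; ties among case event times are
  processed in ascending (time, subject id) order. Stored times are
  never jittered.
- Exact categorical matching only (the designs of interest have 3–6
  well-filled categories); no caliper matching.
- Under `case_fraction < 1` the closed-form product runs over sampled
  cases, and control rescaling still targets the full cohort's control
  count (the natural generalization; the typical case is the documented
  one).
- Model-based probability clipping (`[1e−6, 1]`) guards inversion
  against fitted tails; GAM predictions clamp out-of-range times to the
  training range.
- Degenerate inputs: empty strata and undefined ratios yield NaN with a
  warning rather than an exception; zero sampling probabilities, empty
  risk-set products and invalid configurations raise with the offending
  subject or field named.
- The package is a library: the importable API plus the `examples/`
  scripts are the intended interface; there is no shell CLI.

## Known limitations

- Point estimates only for the calibration slope (no sandwich variance).
- The closed-form weights assume the realized design matches the
  declared one; a mismatch is detected only when a sampled control is
  ineligible for its own set.
- Logit-linear ("glm") weights can shift absolute-risk-scale metrics by
  a few percent relative to closed-form or spline weights when the
  inclusion-probability curve is strongly non-logistic in time; the
  spline variant is preferred when in doubt.
- Orphan replacement approximates replacement controls' inclusion
  probabilities by the closed form; the weight-sum guard bounds, but
  does not eliminate, the approximation.
- No competing risks: metrics and sampling would both need
  cumulative-incidence replacements.
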