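# Methods

## Problem and data model

The package analyses longitudinal coded-event tables from primary-care
electronic records: one row per occurrence of a diagnostic code in a
patient's record, with the patient's family practice and the event date.
A study cohort is defined by the presence of at least one qualifying code
inside a study window; the date of the first such code is the patient's
*index date*.  Each code is then scored per patient as endorsed (1) or not
(0), an endorsement being at least one occurrence in the closed window
`[index, index + w]` days.  The default `w` is 30 days, the conventional
horizon within which codes registered for the same clinical event cluster;
`w = "ever"` scores any occurrence on or after the index date.  Repeat
records of the same code on the same date are administrative duplicates
and are removed first.  Patients whose recorded death precedes their index
date are excluded as a data-quality rule.  Codes endorsed by nobody are
dropped from the matrix with a logged notice rather than an error, since
code lists are routinely much larger than the observed set.

Two deliberate boundary choices: the endorsement window is *closed* on
both ends (day-granularity data make inclusive bounds least surprising),
and codes recorded before the index date only ever contribute by defining
the index date itself — endorsements are counted from the index date
onward.

## Item-response models

Endorsements are modelled with unidimensional logistic item-response
models.  For the 2PL, the probability that subject *s*'s record contains
code *i* is `logit P = α_i (θ_s − β_i)` with trait `θ_s` standard normal;
the 1PL constrains all slopes equal (one shared α plus per-code β, so a
model with *m* codes has *m* + 1 free parameters and the 2PL-vs-1PL
comparison has *m* − 1 degrees of freedom); the 3PL adds a lower asymptote
`γ_i ∈ [0, 0.5]`.

Estimation is marginal maximum likelihood: the trait is integrated out
over its prior, discretised on a quadrature grid of 21 equally spaced
nodes on [−6, 6] with standard-normal weights renormalised to unit mass
(size and range configurable).  The trait metric is identified by fixing
the prior to the grid (mean 0, SD 1); a joint shift of all locations and
the grid leaves the likelihood invariant, and this is asserted in tests.

The fitting loop is Bock–Aitkin EM.  The E-step computes each patient's
posterior over the nodes in log space (stable for arbitrarily rare codes
and all-zero response rows) and accumulates expected trials `n_k` and
expected endorsements `r_ik` per node.  The M-step maximises the weighted
Bernoulli likelihood per item: damped Newton in slope–intercept space for
the 2PL (step-halving on the objective guarantees ascent, hence monotone
deviance across EM cycles, also asserted in tests); coordinate Newton
sweeps alternating per-item intercepts with the shared slope for the 1PL;
bounded L-BFGS-B with a weak Beta(1.25, 6) prior on the asymptote for the
3PL (the prior keeps γ off degenerate corners; the plain deviance can
therefore rise by a prior-scale amount in a 3PL cycle while the penalised
objective still ascends).  After EM, up to `max_newton` polish cycles take
a single safeguarded Newton step per item against freshly computed
expected counts.  Estimation stops when the largest absolute parameter
change in a cycle falls below the convergence criterion; the defaults
(criterion 0.01, 20 EM cycles, 2 Newton cycles) reproduce a classical
calibration-program regime, and non-convergence within the budgets is
reported in the results object, not raised.  Tight tolerances for oracle
comparisons are passed explicitly by the tests.  Initial values are
deterministic: slopes at 1, locations at the normal quantile matched to
the observed endorsement rate; there is no randomness in the fitter.
Slopes are clipped to [1e−3, 60]; an optional lognormal slope penalty
(off by default, and off in all acceptance checks) can stabilise items
endorsed by a handful of patients.  Items with fewer than 5 endorsements
are flagged `low-information`, never silently dropped.

Before fitting, codes are screened on the item-rest correlation — the
Pearson correlation between a code's indicator and the sum of all other
codes.  Codes below the −0.15 threshold are outside the measurable range
of the trait (typically the very frequent, near-synonymous codes, which a
record contains *instead of* other codes) and are excluded with the
correlation recorded; zero-variance codes are excluded as degenerate.
Calibrated plus excluded codes always cover the input code set.

### Standard errors

Standard errors come from the observed (Louis) information of the
marginal log-likelihood: the posterior-expected complete-data information
minus the posterior covariance of the per-patient scores, assembled over
*all* items — including cross-item blocks, which are exact for the 1PL/2PL
(canonical link) — then inverted and mapped from slope–intercept to
slope–threshold parameterisation by the delta method.  On a three-item
test problem this reproduces a finite-difference Hessian of the marginal
log-likelihood to about six decimal places.  (A two-item 2PL is not
identified — four parameters against three response-pattern degrees of
freedom — which is why the smallest test problem has three items.)  For
the 3PL the complete-data term uses the Fisher (expected) form.  A
singular information matrix yields missing standard errors with a
warning, not a crash.  Rare codes get large standard errors, the expected
information-monotonicity pattern for items far out on the trait.

### Trait scores

EAP scores are the posterior mean of θ over the grid per response
pattern, with posterior SDs; they are computed from the final E-step at no
extra cost.

## Fit diagnostics

### Item fit

For each item the package computes an interval likelihood-ratio
chi-square: patients are grouped into (default 10) equal-mass intervals of
their **leave-one-out** EAP — the posterior mean given every *other*
item's responses — and observed endorsement counts per interval are
compared with the leave-one-out expectations `E[x_si | rest]`, using
`G² = 2 Σ [r ln(r/E) + (n−r) ln((n−r)/(n−E))]` with the `0·ln 0 = 0`
convention, referred to chi-square with (intervals after merging) −
(item parameters) degrees of freedom.  Two construction details matter:

* Leaving the tested item out of both the grouping and the expectation is
  essential.  Scores computed *with* the item condition on the very
  response under test; the resulting selection bias inflates the statistic
  roughly tenfold even when the model is correct.  With the leave-one-out
  construction the statistic's null mean matches its degrees of freedom to
  within ~1% at 20 items × 2,000 patients (parametric bootstrap), while a
  deliberately non-monotone item is flagged far above the bootstrap 99th
  percentile.
* Intervals are formed by equal-mass binning that never splits tied
  scores (sparse matrices put most patients on a handful of identical
  response patterns), and the leave-one-out EAP is rounded to 10⁻⁸ before
  binning so patients with identical rest-patterns are exact ties — the
  arithmetic otherwise leaves response-dependent rounding noise that would
  leak the tested item back into the grouping.

Adjacent intervals are merged until every expected endorsement count
reaches 5 (configurable); items left with fewer than two intervals, or
non-positive degrees of freedom, report a missing statistic with a reason.
Since many items are tested, a Benjamini–Hochberg adjusted p-value column
accompanies the raw one.  `item_fit_reference` provides the parametric
bootstrap of the statistic (traits redrawn from the prior, responses from
the fitted curves, model refitted per replicate) for calibration checks
and empirical critical values.

### Model comparison

Nested fits (1PL ⊂ 2PL ⊂ 3PL) are compared with the likelihood-ratio
chi-square on the free-parameter-count difference.  `fit_nested_pair`
warm-starts the general model from the restricted solution, which
guarantees a non-negative statistic.  Under common-slope data the
2PL-vs-1PL statistic is approximately chi-square distributed: its mean
matches its degrees of freedom within Monte-Carlo error at 20 items ×
2,000 patients.

## Intraclass correlation

Between-practice variation in the use of a code is quantified with the
one-way random-effects ANOVA (method-of-moments) estimator applied
directly to the 0/1 endorsement indicator, with the standard adjusted
mean group size for unbalanced practices; negative estimates are truncated
to zero and practices with fewer than two cohort patients are excluded
(and reflected in `n_practices_used`).  The estimator agrees with a REML
linear mixed-model fit to well within 0.03 on simulated clustered data.
Relative frequencies are shares of deduplicated occurrences over the
scoped codes; in ICC tables built from the matrix alone, shares of
endorsements are used instead and labelled as such.  The ICC is computed
on the same windowed matrix used for calibration by default (a flag on
the matrix-building step switches to ever-recorded endorsement).
Model-based ICCs (logistic random-intercept / latent-threshold π²/3) are
out of scope.

## Synthetic data generator

No patient-level extract of this kind can be shipped, so the generator is
a first-class module and every downstream stage is tested against data
with known truth.  The base mechanism draws `θ_s ~ N(mean, sd)`, assigns
patients uniformly to practices, and endorses code *i* with
`logit = α_i (θ_s − β_i) + e_{p(s), i}`, where the practice effect
`e_{p,i}` is i.i.d. normal with SD `practice_sd` — an item-intercept
shift, not a trait shift, because between-practice variation in real
records reflects coding *choice*, not case-mix.  Endorsed pairs get event
dates (index date uniform in the study window, offsets uniform within the
post-index spread, one endorsement anchored at the index date so the
records pipeline recovers the cohort exactly), same-date duplicates are
injected at a configurable rate, and patients with no endorsement are
discarded (default, with a logged count) or redrawn under a bounded
budget.  Identical configurations produce byte-identical files.

The intercept-shift mechanism alone cannot reproduce one salient feature
of real coded records: the strongly negative item-rest correlations of the
frequent codes.  Under any model that is conditionally independent given
(trait, practice), negative patient-level dependence can only come from
between-practice variance, and at realistic ICCs (~0.25) it tops out
around −0.1.  In reality the negative dependence is *per event*: a
clinical event is registered once, so near-synonymous frequent codes
compete for a single slot.  The generator therefore offers a
*primary-code choice* layer (`choice_block`): each patient records exactly
one code from a designated common block, drawn from a practice-specific
choice distribution (a Dirichlet tilt, strength-scalable, around a shared
geometric frequency profile).  The tilt strength controls the practice
ICC (approximately `strength² / (A + 1)` for total Dirichlet concentration
`A`) independently of the patient-level exclusivity, which is what lets
the preset match moderate ICCs and strong negative item-rest correlations
at the same time.

`paper_like_preset` combines both mechanisms to emulate a national
primary-care stroke extract at desk scale: 20,000 patients (default)
across 100 practices, 110 codes — 8 common near-synonymous codes under
the choice mechanism plus a rare tail whose locations extend to ~10.5
(endorsement probability at the trait mean below 10⁻³ for the extreme
codes) and whose discriminations decline as locations rise.  Under the
default settings roughly 77–82% of patients carry exactly one distinct
code, the commonest codes show ICCs up to ~0.26, the top four-to-seven
codes fall below the −0.15 screen while every rare code is retained, and
a handful of the rarest codes receive no endorsements at all and are
dropped by the records pipeline — the same restriction dynamics seen in
real extracts.  What the generator does *not* emulate: free-text records,
prescriptions/referral streams, registration ("up-to-standard") history,
survival processes beyond an optional death date, and any real code
semantics.  Passing tests therefore demonstrate correctness of the
estimators under the stated mechanisms, not fidelity to any particular
real dataset.

## Numerical choices and limitations

* Probabilities are clipped to [1e−12, 1 − 1e−12] inside likelihoods;
  pattern likelihoods and posteriors are computed in log space.
* Problem sizes in the test-suite experiments (e.g. 20 items × 2,000
  patients for recovery and calibration studies, 200 bootstrap
  replicates, 20 seeds for null-distribution means) were chosen as the
  smallest sizes at which the asymptotic behaviour under test is cleanly
  visible.
* Real calibration programs of this era reported locations of 4.5–11.6
  with a standard-normal prior, which is not reproducible arithmetic under
  the standard metric at the reported frequencies; the package reports the
  standard metric and reproduces the qualitative pattern instead (rare
  codes → extreme locations with inflated standard errors, and a negative
  discrimination–location relationship in the preset's rare tail).
* 3PL asymptotes are weakly identified at desk-scale samples; the Beta
  prior shrinks them toward zero, and their standard errors use the
  expected-information form.
* Multidimensional and four-parameter models, differential item
  functioning across practices, dimensionality/local-independence
  testing, and MCMC estimation are out of scope.
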