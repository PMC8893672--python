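# Methods

This note documents the modelling choices behind `coclaims`: what each
stage computes, the conventions adopted where the underlying study design
leaves room, what the synthetic generator does and does not emulate, and
the numerical details a reviewer would want pinned down.

## Data model

Five linked tables (person registry, physician service claims,
prescription dispensations, hospital discharge abstracts, ED visits) are
exchanged as RFC-4180 CSV with ISO-8601 dates and empty fields for missing
values; coverage intervals are flattened to a companion `coverage.csv`.
Validation is strict (a malformed value raises an error naming file, row
and column) but never silently drops data: claims whose person id is
absent from the registry are retained and listed in an integrity report.
Provider specialty is a claim-level field — a provider's recorded
specialty could in principle vary across claims — and the usual-care-
provider logic uses the claim-level value throughout.

One tablet is one day of supply (once-daily statin dosing), so days
supplied are derived from quantities dispensed and no days-supply field is
stored.

## Cohort construction

New users: earliest statin dispensation (by configurable DIN list) inside
the accrual window, with no statin dispensation in the five years before
that date.  Follow-up is the half-open window `[index, index + 365 days)`.

Seven exclusion criteria are applied **in a fixed order with
first-failure attribution**, so the flow report is a waterfall: (1)
missing birth date or sex; (2) age under 18 at index (integer years,
floored); (3) coverage not continuous over `[index − 5y, index + 365d)` —
the union of closed coverage intervals must contain every day, a
single-day gap counts as a gap, and a `grace_days` parameter (default 0)
can relax this; (4) any long-term-care admission in the same window; (5)
out-of-province hospitalization during follow-up; (6) a pregnancy-prefix
diagnosis in service claims, hospital abstracts or ED visits within
±365 days of index, both endpoints inclusive; (7) zero eligible GP visits
during follow-up.  Death during follow-up is folded into criterion 3,
since registry coverage ends at death.

Two conventions deserve a note.  The hospital-abstract schema carries no
facility-province field, so criterion 5 is detected from in-hospital
service claims billed by out-of-province providers.  And criterion 7 uses
the same visit-eligibility filter as the continuity measures (valid,
outpatient, in-province, deduplicated GP claims), which guarantees every
cohort member has `N ≥ 1` when the UPCI is computed.

Covariates follow the five-domain framework common in adherence
modelling: demographics at index (age, sex, residence, neighbourhood
income quintile with an explicit missing level); prior-year counts over
`[index − 365d, index)` of deduplicated GP and specialist visits, acute
hospitalizations, ED visits, and distinct drugs (by DIN); the
cost-weighted fraction of dispensed cost paid by government insurance
(0 when there were no dispensations); a Charlson score computed as the
sum of configurable ICD-prefix weights over distinct matched conditions
in the prior year; and chronic-condition flags matched by ICD prefix or
DIN over history back to a floor date (default 1996-01-01, inclusive of
the index date).  The shipped code lists are deliberately small synthetic
stand-ins; real analyses should supply validated definitions via
`codelists.yaml`.

## Continuity measures

Eligible visits are deduplicated `(GP, date)` pairs from valid,
outpatient, in-province claims in follow-up.  `UPCI = n_max / N` is exact
rational division (`upci_fraction` exposes a `fractions.Fraction` for
drift-free invariant checking).  The high/low split uses the cohort
percentile of the analyzed cohort's UPCI values with numpy's linear
interpolation (type-7) quantile — the quantile definition is a
convention, so the realized threshold is recorded in the run metadata —
and `high` means UPCI **≥** threshold, putting tie mass on the high side.

USP and CMEP sets allow any specialty; CME claims must also be valid and
in-province.  The integrated flag is the existential intersection: it is
true when *some* provider is simultaneously in the usual-care set, the
USP set and the CMEP set **and** is a GP.  With tied usual-care providers
this is the only well-defined reading; the profile table records the tie
count so analysts can restrict to single-UCP patients if they prefer a
stricter reading.

## Adherence

Primary (`accumulate`): covered days are the truncated tablet total —
for each follow-up dispensation, `min(quantity, days from dispensation to
window end)` — with same-day dispensations pooled first (this makes PDC
invariant to splitting a dispensation across products, the natural
reading of "switching allowed").  `PDC = min(1, covered / (365 −
hospital days))`.  The cap at 1 is a convention (a proportion cannot
exceed one) and never changes the ≥ 0.80 classification; it can be
disabled for audit.  Truncation counts calendar days remaining,
ignoring hospital days, which only shrink the denominator.

Hospital days merge overlapping stays, count the admission day but not
the discharge day, and include alternative-care stays by default (the
patient is still not self-administering); an acute-only switch exists.
Hospitalized days are not added to the numerator (no assumption of
in-hospital supply).  A denominator below one day (the whole year in
hospital) yields an undefined PDC; such members are dropped from models
with a logged count rather than scored 0.

Sensitivity (`no_carryover`): each dispensation opens
`[date, date + quantity)` and a new dispensation resets coverage,
discarding the remainder of the previous supply; covered days are the
reset-union intersected with the window.  Non-overlapping refills make
the two variants identical, and no-carryover is never larger.

Both variants are checked against independent day-by-day tablet-walk
oracles in the tests, and the two differ exactly where stockpiling
matters.

## Statistics

* Proportion metrics use Wilson 95% intervals (at cohort sizes in the
  tens of thousands these are indistinguishable from Wald intervals);
  a metric with a zero margin is reported as undefined rather than 0/0.
* Cohen's kappa uses the Fleiss–Cohen–Everitt large-sample variance,
  with the interval clipped to [−1, 1].
* 2×2 odds ratios use the cross-product estimate with the Woolf
  (log-scale normal) interval; a zero cell triggers the
  Haldane–Anscombe 0.5 correction, flagged on the result.
* VIF screening regresses each design column on the others (plus an
  intercept); covariates with VIF > 2.5 are dropped greedily
  (worst first, recompute) and the exposure is never dropped.  Perfect
  collinearity gives an infinite VIF and is removed first.
* Logistic models are maximum-likelihood fits (statsmodels) with Wald
  intervals on `exp(β)`; non-convergence or suspected separation raises
  rather than returning a silent estimate.  The income "missing" level
  is retained as its own indicator.
* AUROC is the Mann–Whitney estimator with ties counted one half; the
  paired comparison uses the DeLong placement-value covariance
  estimator, reported as χ² = Δ²/var(Δ) with one degree of freedom.
  Identical predictions give Δ = 0, p = 1 by convention.  The
  implementation is cross-checked in the tests against brute-force pair
  counting, scikit-learn's AUROC, a paired bootstrap, and R's pROC
  `roc.test`.

Reports apply small-cell suppression: any displayed count below the
threshold (default 6) is masked along with its percentage, and when a
group's total is disclosed a second cell is masked so the first cannot be
recovered by subtraction.  Bundles are tidy CSVs plus a JSON metadata
file (plan, realized UPCI threshold, dropped covariates, config digest);
identical inputs give byte-identical bundles.

## Synthetic generator

Each patient carries a latent coordinated-care flag `C` (prevalence
0.28 by default).  Coordinated patients direct GP visits to a principal
GP with high loyalty (0.95 vs 0.50), have that GP prescribe their statin
(0.90 vs 0.35) and bill a CME (0.95 vs 0.25); specialists bill rare
background CMEs (0.02).  Visit-day counts are Poisson (mean 6/year for
GPs, floored at one visit so the no-GP-visit exclusion is not triggered
by construction; 3/year specialists), hospitalization and ED rates 0.25
stays/visits per two-year window, with ~20% of patients seeing ≥ 1 of
each — roughly the shape of the cohort the analysis targets.  A small
fraction of duplicate same-day claims (4%) and invalid-flagged claims
(2%) exercise the eligibility filters; CME claims are kept valid so that
perfect-fidelity arm settings map `C` exactly onto the computed
integrated flag.

Optimal adherence is drawn from `logit p = β₀ + β_C·C + covariate
terms` (defaults: β₀ = 0, β_C = log 1.45, small female/age/prior-
hospitalization effects).  Dispensation quantities are then back-solved
so that the PDC algorithm reproduces the drawn outcome exactly under
*both* PDC variants: adherent patients refill 90 tablets at slightly
jittered sub-90-day intervals spanning the window (the final refill
straddles the window end, exercising truncation and the cap), while
non-adherent patients receive consecutive refills totalling strictly
less than 80% of their hospital-adjusted denominator.  Planting the
effect on the binary outcome makes `exp(β_C)` the exact estimand for
recovery tests.  One RNG stream per table, seeded from `params.seed`
via fixed offsets, keeps tables stable as the roster grows.

`perturb_for_exclusions` appends patients who each violate exactly one
exclusion criterion (and pass all earlier ones), returning the injected
ids so the flow report can be cross-checked cell by cell.

What the generator does **not** emulate: real prevalence, fee schedules,
ICD frequency distributions, provider-level clustering, seasonal refill
behaviour, or informative censoring.  Passing tests therefore demonstrate
the *correctness of the pipeline's logic and estimators* under the stated
statistical structure, not the external validity of any effect size on
real claims.

## Verification strategy and problem sizes

The published cohort itself is confidential, so the quantities that are
recomputable at desk scale are the ones derived from printed counts: the
two unadjusted odds ratios with their Woolf intervals and the headline
percentages (the printed counts are embedded as inputs, and the report
layer recomputes from them at run time).  Everything that depended on the
real cohort is verified as properties on synthetic data: planted-OR
recovery uses 20 replicates of 20,000 patients; null calibration uses 80
replicate cohorts of 2,000 (tests) or 60 (acceptance script); the DeLong
variance check uses n = 500 with a 2,000-replicate paired bootstrap; PDC
oracle agreement uses 1,000 random refill histories.  These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands while
keeping a full run in the minutes range on a single core.

## Known limitations

* Associations estimated by the pipeline are not causal; receiving all
  services from one GP may mark, rather than make, a good relationship.
* Salaried physicians who bill no service claims would depress visit
  counts in real data; the generator does not model payment schemes.
* The Charlson map and condition definitions shipped as defaults are
  synthetic toy lists, not validated case definitions.
* Area-level income quintile is treated as an input field; no postal-code
  linkage is performed.
* The flow report counts exclusions per criterion under first-failure
  attribution; patients failing several criteria are counted once, so
  per-criterion counts are attribution-order dependent by design.
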