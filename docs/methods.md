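# Methods

## The model

Follow-up after elective aortic surgery is discretized into intervals of
`interval_length` months (default 6, the standard first-visit schedule) up
to a `horizon` (default 36 months, six steps). At each interval boundary a
patient occupies one of four mutually exclusive states — healthy (H),
complication (C), reintervened (R), dead (D) — and movement across interval
*k* is governed by its own 4×4 row-stochastic matrix `P_k`. A
non-homogeneous chain is used because event and reintervention rates in
surveillance cohorts are visibly front-loaded: a single time-constant matrix
would flatten exactly the feature the first-visit question turns on. A
6-month step keeps one matrix per scheduled visit; a finer step would chase
noise in small interval counts.

Assumptions baked into the state space:

* **Monotone severity, no recovery.** Allowed transitions are
  H→{H,C,R,D}, C→{C,R,D}, R→{R,D}, D→D. "C" means *ever* complicated (and
  not yet reintervened), "R" *ever* reintervened; a resolved endoleak does
  not return a patient to H. This matches cumulative-frequency reporting and
  makes D occupancy non-decreasing and H occupancy non-increasing, which the
  code enforces as invariants.
* **First-order dynamics per interval.** Within an interval, only the state
  at its start matters. No covariate adjustment is attempted; with a few
  hundred patients the per-interval risk sets for C and R are too small to
  support regression structure.
* **Worst state wins within an interval.** A patient with a complication and
  its reintervention inside one interval lands directly in R; the states
  stay mutually exclusive.

## Outcome derivation and eligibility

Aortic events are any new endoleak (I–IV), a new or anastomotic aneurysm, or
diameter progression ≥ 10 mm **versus the immediate postoperative
baseline** (not the previous visit). Sub-threshold progression entries are
ignored at derivation. The primary composite takes the earliest of aortic
event / reintervention / death, with severity (death > reintervention >
aortic event) breaking exact ties. Times are months from discharge; a
visit-detected event carries the visit time, and interval-censored onset is
deliberately not back-imputed — the model's interval resolution absorbs it.

The eligibility cascade excludes, in fixed order: age < 18, history of
aortic dissection, planned further aortic surgery, emergent surgery,
in-hospital aortic event, and fewer than two CTA follow-up visits. The order
is a package convention (each patient is tallied under the first criterion
that catches them) so exclusion tallies are deterministic; the eligible set
itself is order-independent.

## Estimation and censoring conventions

Interval boundaries use half-open intervals `(t, t + 6]`: an event at
exactly 6.0 months counts at the first visit, so "at 6 months" summaries
include that visit's findings. Per interval and origin state,

```
p(origin → dest) = transitions / (n_at_risk − n_censored_in_interval)
```

A patient censored strictly inside an interval is dropped from that
interval's denominator (complete-case within the interval) and is absent
thereafter; a death inside the interval is always a fully observed
transition to D, since death ascertainment does not depend on imaging.
Origins with an empty effective risk set get the identity row — no
information moves nobody — with a logged warning rather than an error,
because late intervals in small strata routinely have empty C or R sets.
Estimated matrices are validated for row-stochasticity (tolerance 1e-12)
and structural zeros; occupancy rows must sum to 1 within 1e-9.

Exact occupancy is the left matrix product of the estimated chain from the
initial distribution (everyone healthy at discharge). Simulation draws each
patient-step from the row of the current state via one uniform per step,
seeded with `numpy.random.default_rng(seed)`; its occupancy rows are exact
relative frequencies and converge to the propagated values at the binomial
rate.

## Kaplan–Meier estimator

Implemented from scratch (the product-limit formula over the observed time
grid), with the standard events-before-censor tie convention: subjects
censored at time *u* remain at risk for events at *u*. Confidence bands are
Greenwood's variance transported to the log(−log) scale, which keeps the
95% band inside [0, 1]; at S = 1 the band collapses to (1, 1) and at S = 0
to (0, 0). The test suite checks exact agreement (≤ 1e-10) with lifelines'
`KaplanMeierFitter` on randomized censored datasets; lifelines is used only
as an oracle, never in the computation path. Risk tables are reported on the
6-month grid; the grid's `n_risk` column counts subjects still under
observation *after* accounting for the grid time itself, consistent with the
`(t, t+6]` interval convention.

## Number needed to harm

NNH at step *m* over harm set *S* is `1 / Σ_{s∈S} π_m(s)`, the reciprocal of
the probability of occupying a harm state at the skipped visit. This is a
worst-case equation of occupancy with missed-visit excess risk: it assumes
every harmful finding at the skipped visit would otherwise have been acted
on, and that none is caught between visits. Every NNH report row carries
this assumption as text. Both the two-decimal reciprocal and its ceiling
(whole patients) are reported; zero harm occupancy raises an explicit
"NNH undefined" error instead of returning infinity. Subgroup NNH refits
the chain per stratum and applies the same reciprocal.

## Synthetic cohort generator

Real surveillance data of this kind are not distributable, so the generator
produces cohorts with the statistical structure the analysis assumes:
default 464 patients, 25% endovascular, abdominal pathology in 33% of open
and 81% of endovascular patients (≈ 45% overall), ages centred in the
mid-60s (open) and mid-70s (endovascular), and per-interval transition
hazards for H→C, H→R, H→D, C→R, C→D, R→D. The default hazards are
front-loaded (H→C of 2.6%/3.4% in the first year, decaying to 0.5%; a
flatter, slowly rising death hazard) — values chosen once as a realistic
elective-aortic-surgery profile, not a reconstruction of any study's
unpublished matrices. An optional endovascular-specific hazard set emulates
the higher early complication rate after stent grafting; cohort-level
ground-truth occupancy is then the approach-fraction mixture of the two
propagated chains.

Per patient and interval the generator draws an administrative-censoring
Bernoulli first, then a single categorical transition among
{stay, →C, →R, →D} with the configured hazards. Keeping the censor draw
independent makes the observed transition fractions unbiased for the
hazards, so parameter-recovery tests are sharp; folding censoring into one
five-way draw would shrink every observed hazard by the factor
(1 − censor_prob). A censor draw ends follow-up at the interval *start* —
the interval's transition is never observed — mirroring the estimator's
denominator convention. Default censoring is 0 for the first two intervals
(the first two visits are treated as complete-case) and rises steeply after
18 months (5%, 15%, 20%, 25% per interval), emulating the attrition typical
of long-term surveillance. With `detection="visit"` (default) event times
are recorded at the interval-end visit; `"exact"` draws them uniformly
inside the interval. Patients who die before their second visit keep the
two-visit imaging minimum so the eligibility cascade does not induce
survivorship bias in generated cohorts.

Each patient consumes a dedicated substream keyed by `(seed, index)`
(`default_rng([seed, i])`), so cohorts are bit-reproducible and stable under
reordering or truncation. Records carry the true generating state
trajectory, used by tests as a recovery oracle and never by estimators.

What the generator does **not** emulate: correlations among baseline
covariates, covariate-dependent hazards, informative censoring, measurement
error in diameters, or between-visit event detection. Tests passing on
synthetic cohorts therefore demonstrate correctness of the estimators and
pipeline under the model's own assumptions, not robustness to their
violation in real data.

## Problem sizes and numerical choices

Parameter-recovery tests use a 50,000-patient cohort over six intervals,
with every allowed transition cell required to lie within 3 binomial
standard errors of its generating hazard and end-to-end occupancy within
0.5 percentage points per cell. Simulation-consistency tests use the
10,000-patient simulation size with a 3·sqrt(p(1−p)/n) per-cell bound.
Hypothesis-based property tests run derandomized. CSV readers use pandas'
round-trip float parsing so written bundles reload to the exact binary
values; report bundles contain no timestamps and are byte-identical for
identical inputs and seed.

## Known limitations

* The worst-case NNH reading gives a lower bound on the true NNH of
  skipping a visit; any between-visit detection raises it.
* Complete-case handling of within-interval censoring assumes censoring is
  non-informative; informative drop-out would bias late-interval matrices.
* Identity rows for empty risk sets understate movement in sparse strata;
  subgroup NNH from small strata should be read with corresponding caution.
* Eligibility, discretization and estimation assume the cohort file's event
  log is complete up to the recorded follow-up end; no imputation of any
  kind is performed.
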