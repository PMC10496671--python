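# Methods

## The model

`careflow` simulates the cohort of callers to an urgent-care telephone
triage line (NHS 111) who are triaged to a **primary-care disposition**
— a recommendation to contact a GP or allied primary-care service within
a stated timeframe, face-to-face or remotely.  Each caller is tracked
for at most 72 hours after the index call as they move among six
services: the index 111 call, primary care, emergency department (ED),
emergency ambulance (999), in-patient admission and subsequent 111
calls, with "no further contact" as the absorbing exit.

One run covers one simulated year and has four stochastic layers:

1. **Arrivals.**  Index calls form an inhomogeneous Poisson process with
   piecewise-constant intensity on 192 strata: hour of day (24) x
   calendar quarter (4) x weekend flag (2).  The parameter table stores
   the *mean inter-arrival time in minutes* per stratum; `+inf` encodes
   a stratum with no arrivals.  Sampling uses exact thinning: candidates
   are drawn at the fastest stratum's rate and accepted with probability
   `rate(t) / rate_max`.  (A cheaper stratum-of-draw variant — each gap
   drawn at the rate of the stratum the clock is in — is retained behind
   `method="stratum_of_draw"`, but it systematically undercounts the
   first minutes of any hour whose rate jumps sharply upward, e.g. the
   morning ramp, by enough to matter: ~17% at a 70% rate step.  Thinning
   is unbiased and exactly Poisson in the homogeneous case.)

2. **Triage.**  Each caller draws a disposition code in proportion to
   the disposition weights.  The code fixes the contact timeframe (60 to
   1440 minutes here) and the probability `p_timely` that the
   primary-care contact actually happens inside that timeframe; the
   timely flag is a Bernoulli draw per caller.

3. **Trajectory walk.**  From the current service the next service is
   drawn from a transition row keyed by (current service,
   `gp_first_contact`, quarter of the index call).  `gp_first_contact`
   is defined by the *realised* first transition: true iff the caller's
   first post-index contact is primary care.  Because the first
   transition defines the flag, the INDEX_111 row is the *marginal*
   first-contact distribution, stored identically under both flag
   strata; the engine reads the `gp=False` stratum for the first hop.
   Every hop samples a queue time (wait between services, keyed by the
   from/to pair) and an activity time (contact duration, keyed by the
   destination) from fitted parametric distributions.  An event whose
   start would exceed index-time + 72 h is discarded and the caller
   exits; a drawn "no further contact" exits immediately.  ED
   attendances draw an avoidable flag from `p_avoidable` keyed by
   (disposition code, `gp_first_contact`); the avoidable definition is
   the O'Keeffe one — a type 1 ED attendance using no investigations,
   treatments or referral requiring type 1 facilities.

4. **Timely mechanism.**  The timely flag is made behaviourally real
   through the first-hop queue draw when that hop is primary care:
   timely callers' queue draws are rejection-sampled until the contact
   starts inside the timeframe, non-timely callers' until it starts
   outside (1000 attempts, then a uniform fallback on the feasible
   side).  The two-sided rule makes the flag fully observable in the
   emitted event log, which is what lets the estimator recover
   `p_timely` from data; with a one-sided rule the flag would be
   confounded with chance early arrivals.  Correspondingly, the
   estimator's default `p_timely` conditions on callers whose first
   contact *is* primary care (`among="pc_first"`); the all-caller
   variant (`among="all"`, callers who never reach primary care counted
   as not timely) is available but does not round-trip.

Callers are mutually independent — the system carries no capacity
constraints or shared resources — so each caller runs on a dedicated
child random stream spawned from the run seed.  Runs are bit-for-bit
reproducible and per-caller trajectories are invariant to other callers,
which makes common-random-number scenario coupling exact up to the
point where a scenario changes a caller's own draws.

## Calendar

Time is minutes from t = 0 = 00:00, 1 January of a non-leap year whose
1 January falls on a configurable weekday (default Friday).  Quarters
are the true non-leap calendar blocks of 90/91/92/92 days; the weekend
flag covers Saturday and Sunday.  A trajectory's transition lookups use
the quarter of its index call (trajectories span at most three days, so
boundary crossing is ignored).

## Duration models and SSE selection

Queue and activity durations are fitted by scanning six candidate
families — exponential, gamma, lognormal, normal, uniform, Weibull —
estimated by maximum likelihood (location pinned at zero for the
non-negative families, method-of-moments fallback if the optimiser
fails), and scored by the sum of squared errors between the empirical
density histogram (100 equal-width bins spanning [min, max]) and the
fitted pdf at bin centres.  The lowest SSE wins.

Two numerical details matter.  First, gamma and Weibull nest the
exponential, so on exponential data all three fitted densities coincide
and their SSE differences are pure histogram noise; a strict argmin
would pick among them at random.  The SSE of a well-specified fit
fluctuates at the histogram's multinomial noise floor, approximately
`1/(n * w^2)` for `n` samples and bin width `w`, so a family with fewer
parameters is preferred whenever its SSE is within one noise floor of
the minimum (`parsimony_mult=1`; set 0 for a strict argmin).  Misfit
families sit orders of magnitude above the floor and are never
promoted; in calibration, the generating family is selected 20/20 times
for every family at n = 10 000.  Second, sampling rejects negative
draws (possible under the normal family) up to 1000 times and then
clamps to zero.

Fitting requires at least 30 samples (fewer raises an error advising an
empirical fallback; the bundle estimator substitutes an exponential at
the sample mean and records the substitution in provenance) and refuses
zero-variance data.

## Estimation from an event log

Every model parameter is estimable from a linked patient-level event
log (one row per service contact: pseudonymous patient id, timestamp,
service, disposition code on the index row, ED resource flags, optional
end timestamp):

- arrival means = stratum exposure minutes / stratum index-call count
  (`+inf` where no calls; a warning lists entirely uncovered quarters);
- transition rows = empirical next-service frequencies, absence of any
  further event in the 72-h window counted as exit; sparse rows fall
  back (same service pooled over quarters, then over everything, then
  an absorbing exit), each fallback recorded in provenance;
- disposition weights = code frequencies among index calls;
- timely proportions as described above;
- avoidable proportions = classified fraction per (code, flag), with
  unclassifiable ED rows excluded and counted, and empty strata filled
  from the code's pooled value;
- queue samples = gaps from the previous contact's end (or start, where
  no end is recorded) to the next contact's start; activity samples =
  contact durations where end timestamps exist (absent ends degrade
  gracefully to zero-duration activity models, flagged in provenance).

Duration samples are deterministically subsampled to at most 10 000 per
key before family fitting; beyond that size the fit is
sampling-noise-limited anyway and the cap keeps full-bundle estimation
to roughly a minute.

## The what-if scenario

The counterfactual asks what the year would look like if *every* caller
received a timely primary-care contact, with no capacity constraint.
It is implemented as: every `p_timely` set to 1, and the first
transition out of the index call forced to primary care (the only
reading that guarantees 100% access); subsequent transitions proceed
from the `gp_first_contact = true` stratum unchanged, so later ED/999
contacts — and exit — remain possible.  The transformation is
idempotent and touches no other table.

## Replication and reporting

Each scenario is replicated (100 one-year runs by default) with
distinct per-run seeds derived deterministically from a master seed.
Every count is summarised as mean and 95% CI using the normal
approximation `mean ± 1.96 sd/sqrt(n)` (at n = 100 a t-quantile differs
by < 1%; the choice is recorded in report metadata).  Base and what-if
runs are paired by index — the variance-reducing choice under shared
seed derivation — and compared per service as a mean difference
(what-if − base) and a mean percentage change on the *ratio* scale
(100 = no change, 200 = doubling).  If any base run has a zero count
for a service its percentage change is reported as NaN with a warning.
Trajectory tables aggregate each caller's first five interactions
(padded with a terminal exit where shorter) for Sankey-style rendering,
and hourly profiles count index calls per hour x weekday/weekend.

## The synthetic ground truth

Real logs of this kind live in restricted research databases, so the
package ships an invented but realistic ground-truth bundle used by the
test suite and the acceptance script:

- a diurnal arrival curve with morning and early-evening peaks, an
  overnight trough, 1.8x weekend volume and mild seasonal multipliers,
  scaled so the closed-form expected volume is 56 000 index calls/year
  (a plausible one-year regional cohort);
- five dispositions with timeframes 60–1440 min and timely proportions
  0.50–0.70;
- a marginal first-contact row of 47.6% primary care / 38.8% no further
  contact / 10% ED, with a ±0.01 per-quarter tilt between primary care
  and exit so quarters are genuinely distinct;
- transition rows in which callers who reached primary care first are
  lighter ED/999/111 users than those who did not;
- lognormal queue models (means 30–240 min by destination) and service
  activity models (a 5–15 min index call up to a ~24 h in-patient
  stay);
- avoidable-ED probabilities 0.085–0.135 by disposition and flag,
  pooling to ~0.11.

Synthetic logs are produced by simulating a year under this truth and
re-labelling the output into the estimation schema; ED resource flags
are reverse-engineered from each attendance's sampled avoidable label
(avoidable → all three false, otherwise a uniformly chosen non-empty
subset) so the classifier reproduces the simulated labels exactly.

What the generator does *not* emulate: record-linkage errors, opt-outs,
demographic covariates, clinical content of calls, capacity feedback
between services, or secular trend within the year.  Passing recovery
tests therefore demonstrate the internal consistency of
simulator + estimator under the model's own assumptions, not fidelity
to any real population.

## Tolerances in the recovery tests

Parameter-recovery assertions compare the re-estimated bundle with the
truth after one synthetic year (~56 000 callers).  Dense quantities are
held to flat tolerances (marginal first-contact probabilities pooled
over quarters: 0.01; pooled timely/avoidable proportions: 0.02; total
yearly volume: 5%).  Sparse strata cannot meet flat tolerances at this
sample size — an ED-source transition row sees a few hundred
observations, where one binomial SD already exceeds 0.01 — so per-cell
assertions use `max(flat, 4 x sampling SD)` with the SD computed from
the observed cell count: a fixed statistical bound, not a fitted one.

## Problem sizes

The test suite simulates one full synthetic year once (session fixture)
plus many small 2–14-day configurations; the acceptance script runs the
complete pipeline — synthesis, estimation, 30 paired one-year
replications per scenario — which is the replication count the script
defaults to (the `--runs` flag restores any other count; means are
unbiased at any replication count, only CI widths change).

## Known limitations

- No capacity constraints anywhere, including the base scenario: queue
  times are draws from fitted distributions, not emergent from load.
- Ambulance dispatch/conveyance is not modelled; 999 appears only as a
  contact type.
- Caller covariates (age, sex, ethnicity) are out of scope, as is any
  dependence of transition behaviour on them.
- The stratum-of-draw arrival variant is biased at sharp rate steps and
  is kept for comparison only.
- The what-if scenario changes *access*, not case mix: avoidable-ED
  proportions per stratum are held at their base values.
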