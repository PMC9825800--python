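# Methods

## The forced-response design with INC detection

Each respondent holds a private five-digit random number with i.i.d.
uniform digits. The last digit routes the respondent to one of three
questions: a forced-"yes" question (probability p_gy), a forced-"no"
question (p_gn), or the sensitive question itself (1 − p_gy − p_gn).
The sample is split at random (default 50/50, configurable) into two
subsamples g = 1, 2 with different probability pairs; the package default
is (p_1y, p_1n) = (0.1, 0.2) and (p_2y, p_2n) = (0.3, 0.2), the design the
underlying survey used because it maximises the share of honest responders
at the cost of a noisier non-compliance estimate. The digit sets realising
these probabilities are not dictated by the probabilities themselves; the
default uses consecutive low digits ({1}→yes, {2,3}→no in subsample 1;
{1,2,3}→yes, {4,5}→no in subsample 2) and any partition of the right
cardinality is statistically equivalent and can be supplied instead.
Designs with identical probability pairs in both subsamples are rejected:
the three shares are then not identifiable.

Respondents fall into three latent classes per question: compliant
trait-carriers (share θ_y) answer "yes" unless forced-no; compliant
non-carriers (θ_n) answer "yes" only when forced-yes; instruction-non-
compliant respondents (θ_inc) answer "no" always, whether deliberately or
by mistake — both behaviours are observationally identical, so no separate
error model exists. Directed detection of non-compliant *"yes"* answering
is out of scope (it needs far larger samples and the source design could
not estimate it). The observed yes-probability is

λ_g = θ_y (1 − p_gn) + θ_n p_gy.

## Estimation

The two observed rates (λ̂_1, λ̂_2) give a linear system whose solution is
the unconstrained MLE (it reproduces both rates exactly). When it leaves
the simplex, every boundary case is maximised: each single share pinned to
0 leaves a one-dimensional binomial likelihood in an affine rate, which is
concave; we locate the stationary point by 90-step bisection on the
monotone derivative (machine-precision bracket, independent of optimiser
defaults) and re-check the interval endpoints exactly, which also covers
the two-shares-pinned vertices. The highest-likelihood case wins;
likelihood ties within 1e-9 log-units are broken toward the largest
θ_inc — deterministic and conservative about non-compliance — and flagged
as non-unique. With weighted data the same machinery runs on weighted
effective counts (a pseudo-likelihood); uncertainty then comes from the
bootstrap, never from the curvature of the weighted likelihood.

Because non-compliant "no" answers may conceal the trait, the package
reports prevalence bounds [θ_y, θ_y + θ_inc] alongside the point estimate.

An independent grid-search oracle (1e-3 simplex enumeration, in the test
suite only) validates the constrained estimator across random count
configurations.

## Bootstrap inference

Truncation at the simplex boundary skews the sampling distribution of all
three shares and puts an atom at 0 for rare traits, so normal-theory
intervals are inappropriate. Respondents are resampled with replacement
within each randomisation subsample (preserving n_1, n_2), weights
travelling with their respondent as fixed constants (no documented
re-weighting-per-replicate procedure exists, and re-estimating weights per
replicate would mix two sources of uncertainty). Defaults: B = 2000
replicates, 95% percentile intervals (inclusive linear-interpolation
quantiles); percentile rather than BCa because the intervals must respect
the [0, 1] support under heavy boundary skew, and both B and the variant
are configurable. The group difference test resamples both record sets
independently and declares significance when the (1 − α) percentile
interval of the honest-yes difference excludes 0; the report exposes the
honest-no and INC differences too, because an honest-no contrast can be
induced by an INC contrast alone and must not be read as a behavioural
difference on its own.

The resampling unit is the respondent, not the sport record, preserving
within-respondent dependence when one person answered the doping question
for two sports.

## Weighting

Per-question post-stratification aligns each question's responders to
user-supplied population shares over country × gender × age class (weights
are question-specific because item nonresponse differs by question). Cells
are collapsed up a deterministic ladder when population and sample support
disagree — age first (the whole country–gender group collapses, keeping the
weighted margins a proper distribution), then gender, then country — and
every collapse is flagged. Respondents of genders absent from the margins
(intersex, non-binary and transgender respondents were only marginally
present in the source data and carry no population margin) keep weight 1,
flagged, rather than being silently dropped. Weights are normalised to
mean 1. Iterative proportional fitting on the three one-way marginals is
available as an alternative for sparse joints. Whether margins represent
raw populations or recreational-athlete populations is the caller's
choice; margins are an input, not fetched.

## Records, quality control and selection

Quality control drops records with (a) implausible birth-year/education
combinations, via a configurable table of plausible age ranges per
education level (defaults: a doctorate requires age ≥ 24, "in school"
allows ages ≤ 30 — chosen so that a 92-year-old still in school and a
17-year-old doctor are both rejected); (b) a first RRT question answered
in under 15 s; (c) any later RRT question answered in 2 s or less. Timing
rules apply only to questions actually presented; missing times fail the
check by default (conservative, configurable). Every drop is logged with
its triggering rules, and kept + dropped always partitions the input.

Respondents list up to four sports; the doping question attaches to the
two highest-priority sports (competition level first, years played second,
input order breaking exact ties — determinism over hidden randomness).
"Doping" is analysed per sport record (up to two per respondent);
"a doper" is a property of the person, so one record per individual is
selected, preferring a "yes" over a "no" and breaking equal answers with a
seeded uniform draw. Sports map to Artistic / Combat / Games / CGS (sports
measured in centimetres, grams, seconds) / Other via a total, normalised
lookup with Other as default; the shipped starter map covers the common
example sports (fitness sits in Other as it is not decided in cm/g/s —
override via CSV if a different convention is wanted).

## Synthetic surveys

The generator emulates the deposited-data structure: demographics drawn
from a country × gender × age table mirroring the survey's composition,
1–4 sports per respondent (distribution 3404/1478/561/323), competition
levels mostly "didn't compete" (60%), gamma-distributed years played,
per-question five-digit random numbers, and answers drawn from the latent
three-class forward model. Response times are log-normal (median 30 s for
the first RRT item, 10 s later, floored above the QC thresholds) with an
injectable fraction of QC violators (1% hasty, 0.5% implausible
demographics by default) carrying ground-truth flags in a sidecar table
that the analysis pipeline never reads. The INC class is drawn
independently per question by default (the source regimes differ strongly
by question, 8% vs 47%); a respondent-level correlation knob exists,
default 0, because the true within-person dependence is unknown. Item
nonresponse defaults to 2% per question.

Scenario presets pin the true shares to the study's estimated regimes
(honest-yes/INC: 0.104/0.20 over-the-counter medication; 0.44/0.37
medication for other purposes; 0.004/0.08 dopers overall; 0.031/0.12 male
dopers; 0.069 doping in Games; 0.016 doping overall). Where only
honest-yes and INC are reported, honest-no is the simplex complement; the
Games INC share is not separately reported and is set to 0.10, between the
overall (0.08) and male (0.12) doping-question rates.

What passing tests show — and don't: the generator reproduces the
statistical structure the estimator assumes (two-subsample forced
response, latent INC, demographic imbalance, QC contamination), so
recoveries demonstrate correctness of the machinery, not robustness to
snowball-sampling selection, recall bias, country-level attrition or
non-uniform random-number use, none of which are modelled.

## Numerical and test-size choices

- Likelihood tie tolerance 1e-9 log-units; simplex tolerance 1e-9.
- All randomness flows from named integer seeds through
  `numpy.random.Generator`; bootstrap replicates are bitwise reproducible.
- The recovery checks average the estimate over 50 replications of
  10,000-per-subsample simulations: the honest-no/INC shares have standard
  error ≈ 0.02 at that size (θ_n is estimated as 5(λ̂_2 − λ̂_1) under the
  default design), so a single draw cannot test a ±0.015 band; the average
  tests unbiasedness at the same band. The consistency check runs at
  500,000 per subsample for the same reason.
- Bootstrap calibration uses 200 outer replications at 1500 per subsample
  with B = 500; difference-test size and power use 100 repetitions at the
  magnitudes of the Games-vs-overall contrast.
- The acceptance script reports medians over seeded replications (and the
  majority test decision) at the study's sample sizes, because at those
  sizes single-draw noise exceeds some reported values (a 0.4% trait has a
  standard error above 1 point); medians characterise what the method
  typically returns under the stated regimes.

## Known limitations

- Yes-preferred doper selection is a data-construction rule, not an
  estimator correction: when a person's two sport records carry
  independent forced-response draws, preferring "yes" mechanically inflates
  the observed yes-rate, so person-level ("doper") estimates built from
  two-sport respondents carry an upward selection component. The package
  implements the rule as specified and documents rather than corrects
  this; regime recovery checks therefore simulate one record per person.
- Weighted estimation treats weights as known constants; design-based
  variance of the weighting step is not propagated.
- No multiple-testing correction across category contrasts is applied
  (none is defined for the procedure).
- Flat or near-flat likelihoods at the boundary are reported with a
  non-uniqueness flag instead of an arbitrary interior choice; callers
  should inspect the flag for very sparse data.
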