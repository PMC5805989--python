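# Methods

This package implements a longitudinal contact-diary analysis pipeline:
per-diary contact rates, age-mixing matrices against a proportionate-mixing
baseline, an interval-censored exponential model of contact durations,
random-intercept decompositions of contact-rate variance, and two
permutation-null analyses of within-individual persistence.  A synthetic
cohort generator with the same statistical structure makes every stage
testable end to end without access to a real survey dataset.

## Data model and contact rates

A *contact event* is an encounter with a distinct individual or group of
individuals in one geographical location during a reporting day.  Three
per-diary rates are derived:

- **K**, number of contacts: the sum of `group_size` over the diary's
  events — a group event of nine people contributes nine contacts;
- **L**, number of locations: the count of distinct location labels used
  within the diary.  Labels are free-text descriptors and are never
  matched across diaries or participants, because diaries do not identify
  repeat encounters;
- **D**, total contact duration in hours, estimated from categorized
  durations (below).

School and work are merged into one setting stratum for stratified counts
(home / school-or-work / other).  Events with an unrecorded setting or
contact age still count towards K, L and D but are excluded from the
specific stratified analysis that needs the missing field; this maximizes
data use without imputation.  Structurally K ≥ L: every reported location
is defined by at least one contact event there.

## Duration model

Durations are observed only as ordinal categories with known boundaries
(default `<5, 5–14, 15–59, 60–239, ≥240` minutes — the common
contact-survey convention; boundaries are a configuration input and are
echoed into all outputs).  A single exponential rate λ (per minute),
pooled over all contacts, is fitted by expectation–maximization:

- E-step: `E[T | a ≤ T < b] = a + 1/λ − (b−a)·e^{−λ(b−a)}/(1−e^{−λ(b−a)})`,
  reducing to `a + 1/λ` for the open tail;
- M-step: `λ ← N / Σ_c n_c·E[T | category c]`.

The censored log-likelihood is asserted non-decreasing at every iteration
and the fixed point is the interval-censored MLE (cross-checked in the
tests against direct numeric maximization, to 1e-6 relative).  The rate is
non-identifiable when all mass lies in a single non-point interval
anchored at 0 (λ→∞) or in the unbounded tail from 0; both raise errors.

Per-event durations are then imputed from Exponential(λ) truncated to each
event's category interval by inverse-CDF sampling, 200 replicates by
default, seeded per replicate index.  A group event contributes a single
duration regardless of group size.  D per diary is the replicate mean of
the summed event durations; the 2.5/97.5 replicate percentiles quantify
imputation uncertainty.  Events with an unrecorded category are drawn from
the untruncated exponential and flagged.

## Age-mixing matrices

For participant age groups {5–19, 20–39, 40–64, 65+} (participants aged
2–4 are excluded for small samples) and contact age groups {0–5, 6–19,
20–39, 40–64, 65+}:

    ratio(a, b) = share of group-a participants' contacts with group-b
                  individuals ÷ census proportion of group b.

Under proportionate mixing every cell is 1; values above 1 indicate
age-assortative excess.  Confidence intervals are percentile bootstrap
over 1000 resamples of *participants* (each resampled participant carries
all their contacts for the wave); the point estimate is the plug-in value.
Cells for an observed participant group with zero contacts in a contact
group get ratio 0 (with bootstrap CI); groups with no participants are
reported missing.  A touch-only stratification applies the same estimator
to events flagged as involving physical touch.

For cross-wave growth comparison, per-capita contact-rate matrices (mean
contacts per group-a diary with group-b contacts) are collapsed to the
common square grouping {5–19↔6–19, 20–39, 40–64, 65+}, dropping the 0–5
contact column which has no participant-side counterpart.  The dominant
eigenvalue of each wave's matrix — proportional to the epidemic growth
factor under uniform susceptibility and infectivity — ranks the waves.
Only the ranking is interpreted, not the absolute eigenvalues.

## Random-intercept models and variance decomposition

Responses are log(1+K), log(1+D), log(1+L) (and setting-stratified
counts), modelled as Gaussian with fixed effects for age group, sex,
weekday, study wave, the categorized location count {0,1,…,5,6+} (only
for K and D; never for L), optionally categorized household size for the
home-contact model, and a participant random intercept.  Only
participants with ≥2 observations enter the fit.

Fitting is restricted maximum likelihood.  Because the model has a single
variance ratio γ = σ²_b/σ²_w, the REML criterion is profiled analytically
over the fixed effects and residual variance (Woodbury identities reduce
everything to per-participant sums) and maximized over γ by bounded Brent
search to high precision, with the γ=0 boundary checked explicitly.  In
balanced designs this coincides with the closed-form ANOVA estimators,
and the tests cross-check it against an independent general-purpose
mixed-model fitter.  This in-house profile likelihood was chosen over a
generic optimizer because the acceptance surface demands 1e-6 agreement
with the balanced closed form and exact determinism near the boundary.

The variance decomposition reports the between-individual share
σ²_b/(σ²_b+σ²_w) and its complement, the within-individual share.

Covariate effects are reported as **percentage contributions**: the
prediction on the response scale (back-transform exp(·)−1, random
intercept at 0) for a covariate profile, divided by the prediction for
the comparator — a 50-year-old male reporting on a Monday in wave 1 with
household size 1 and a single contact location — times 100.  The
comparator's own profile is 100% by construction.

The published analysis smoothed age with penalized thin-plate splines;
here the default age effect is categorical over the mixing age groups.
The smoothing machinery is off-the-shelf, while the variance and
contribution logic — the substantive content — is unchanged; the fitter
accepts any externally supplied design via the formula hook, so a spline
basis can be plugged in.

## Permutation-null analyses

Both use only participants observed in all four waves, and the same null:
within each wave, permute that wave's observations across participants.
This destroys within-participant linkage while preserving every wave's
marginal distribution exactly (asserted as multiset equality).

**Accumulation / saturation.** Between-participant CV of cumulative rates
at horizons 1..4 (horizon 1 is the plain single-wave CV).  Persistent
individual differences keep the observed CV above the null envelope at
long horizons — the effective contact neighbourhood saturates more slowly
than independent-day mixing would suggest.

**Quantile consistency.** Within each wave participants are assigned to q
equal-count quantiles (ranking with randomized, seeded tie-breaks, since
contact counts tie heavily); a participant is *consistent* if their
quantile is identical in all four waves.  Under the permutation null the
expected consistency is exactly (1/q)^(W−1) for W waves — with equal-count
bins each wave's membership is an independent uniform draw over bins —
which the null simulation reproduces and the tests verify at q = 2 and 4.

## Synthetic cohort generator

The generator emulates the study conditions: 857 households (~1450
members, truncated-geometric household sizes, mean ≈1.7), staggered
household entry over four waves with 30% per-wave dropout and 25%
re-entry (wave sizes ≈1070/910/840/800, ≈370 complete participants),
age structure dominated by 40–64-year-olds, a census-shaped contact-age
distribution, 73.4%/26.3%/0.3% typical/non-typical/unknown day reports.

Rates are generated on the analysis model's own scale.  Locations first:
L ~ zero-truncated Poisson with a participant-level log-normal propensity
(so L also shows between-individual persistence).  Then the latent
Gaussian η = μ_age + β_L·log(1+min(L,6)) + wave + weekday + b_i + ε_ij
sets the contacts *in excess of* the structural one-contact-per-location
minimum: K = L + round(expm1(η)).  Defaults: σ²_b = 0.22, σ²_w = 0.44
(between share exactly 1/3), β_L = 0.5, age-group means chosen so the
mean of participants' means of K is ≈12.5 in ≈2.9 locations.  K is split
into events with ~0.4 group reports per diary of mean size ≈10 (group
sizes capped so the diary keeps ≥L events); contact ages mix a 40%
own-group point mass with the census distribution; true durations are
Exponential(rate 0.0202/min, total ≈9 h/day) and are then binned to
categories, so the duration model's generating assumptions hold exactly.

Two generator choices matter for parameter recovery and were made
deliberately.  Zero-truncating L avoids degenerate all-zero diaries whose
log response is constant; and parameterizing the *excess* over L keeps
log(1+K) a smooth monotone function of the latent Gaussian, so integer
rounding compresses the between- and within-components by the same local
factor and the configured variance *share* survives derivation and
refitting (the components themselves shrink somewhat — a caveat shared
with any log-scale analysis of small counts).  Hard floors (e.g.
K = max(L, ·)) were rejected because one-sided censoring flattens
persistently-low participants and biases the share downward.

What the generator does not emulate: household contact clustering beyond
shared membership, recall and reporting biases, seasonal/holiday effects
beyond a wave-level mean shift, weekday-assignment imbalance across
waves, between-wave changes in assortativity, and zero-contact diaries.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to these real-data features.

## Numerical choices and problem sizes

- EM convergence: relative change in λ below 1e-8, max 10 000 iterations;
  moment-based initial value from interval midpoints.
- Bootstrap and imputation RNG: `numpy` Generator seeded from the run
  seed (imputation replicates via `SeedSequence([seed, replicate])`).
- REML γ search on log scale over e^[−30, 8], Brent tolerance 1e-12;
  boundary γ=0 compared explicitly; rank-deficient fixed-effect designs
  are rejected with the aliased columns named.
- Chi-square homogeneity tests pool sparse tail bins until expected
  counts reach 5; binning is configurable and reported with the p-value
  since any choice is a convention.
- Pearson correlation (Fisher-z CIs) is the default between-wave
  estimator; Spearman available by flag.  Sample (n−1) SD in CVs.
- Default analysis sizes — 857 households, 1000 bootstrap resamples, 200
  imputation replicates, 500 permutation nulls — run in a few seconds;
  tests use smaller panels (100–600 households) chosen to keep
  Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- A single pooled duration rate cannot express setting- or age-specific
  duration patterns (a per-setting extension exists behind a flag).
- The NGM comparison assumes uniform susceptibility/infectivity and no
  reciprocity correction; eigenvalues are comparative only.
- Variance shares are estimated on the log(1+y) scale; for small counts
  the integer nature of K adds within-individual variance that a
  continuous Gaussian model attributes to ε.
- The quantile-consistency tie-break randomization makes observed
  consistency for heavily tied variables depend (slightly) on the seed;
  the seed is recorded in all outputs.
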