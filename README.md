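# contactdiaries

Analysis pipeline for **longitudinal social-contact diaries** — surveys in
which the same participants repeatedly report, for a single day at a time,
every person or group they encountered, where, for how long, and in what
setting.  Such data underpin age-structured models of respiratory-pathogen
transmission: the rate at which people meet, and how that rate varies
between and within individuals over months, shapes both epidemic growth
and the value of single-day (cross-sectional) contact studies.

The package is organised as a library (`src/contactdiaries/`) driven by a
sequence of analysis scripts (`analysis/01…06`) and covers:

- **Contact rates.** From raw contact events, per-diary derivation of the
  number of contacts *K* (group events count all members), the number of
  distinct contact locations *L*, and setting-stratified counts.
- **Duration estimation.** Durations are recorded only as ordinal
  categories; an exponential model is fitted to the interval-censored
  categories by EM and per-event durations are multiply imputed (200
  replicates) to estimate total daily contact duration *D* with
  uncertainty.
- **Age mixing.** Participant-age × contact-age matrices as ratios to
  proportionate mixing (ratio 1 = contacts distributed like the census),
  with participant-bootstrap CIs, a touch-only stratification, and a
  next-generation-matrix ranking of survey waves by dominant eigenvalue.
- **Variance decomposition.** Gaussian random-intercept models for
  log(1+K), log(1+D), log(1+L) with age, sex, weekday, wave and
  location-count covariates, fitted by exact profiled REML; contact-rate
  variance splits into a between-individual share σ²_b/(σ²_b+σ²_w) and a
  within-individual remainder, and covariate effects are reported as
  percentages of a fixed comparator profile.
- **Persistence vs. saturation.** Permutation-null analyses over
  complete-panel participants: the CV of cumulative contacts over 1–4
  waves, and the percentage of participants staying in the same contact
  quantile across waves (null: 100·(1/q)³ for four waves).
- **Synthetic cohort.** A generator producing diary panels with the full
  structure above (857 households / ~1450 people, 30% per-wave dropout,
  long-tailed group-reported contacts, categorized durations, between
  share 1/3), so the whole pipeline is testable without survey data.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```bash
python analysis/01_simulate_cohort.py 1   # seed 1
python analysis/02_contact_rates.py 1
python analysis/05_mixed_models.py
```

prints

```
cohort: 1424 participants in 857 households
diaries per wave: {'R1': 1073, 'R2': 914, 'R3': 837, 'R4': 803}
...
duration model: rate 0.0201/min (mean 50 min), EM 13 iterations
mean of participants' means, contacts: 12.64
mean of participants' means, duration (h): 8.81
mean of participants' means, locations: 2.87
...
[all_days] K: between 33.5% / within 66.5%
[all_days] D: between 16.7% / within 83.3%
[all_days] L: between 13.0% / within 87.0%
```

Reading: the average participant reports ≈12.6 contacts per day across
≈2.9 locations and spends ≈8.8 h in contact; only about a third of the
variance in log contact counts is attributable to stable differences
between individuals — day-to-day variation within the same person
dominates, which is why the remaining drivers compare observed
persistence against permutation nulls (`analysis/06`, where the 4-wave
cumulative CV of 0.656 exceeds the null's 95% bound of 0.497, and 29.6%
of participants keep their contact-rate half vs 12.4% under the null).

Equivalent one-shot run: `contactdiary all --out results/run --seed 1`.

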