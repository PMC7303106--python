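# Methods

## Problem and data model

Clinician ratings of depression (HDRS, 0–52) and mania (YMRS, 0–60) are
collected at up to five outpatient visits over roughly nine months, while
patients file daily smartphone self-assessments.  The pipeline estimates
the ratings from the self-assessments, one day at a time, treating days
independently (no temporal model: a day's estimate uses only that day's
self-report).

Two tables drive everything:

* **self_assessments.csv** — one row per subject-day: activity (−3..+3),
  alcohol units (0..10, 10 encodes "10 or more"), anxiety / irritability /
  cognitive problems / stress (0..2), medicine adherence (taken / omitted /
  changed), mixed mood (0/1), mood (grid −3..+3 with ±0.5 near neutral),
  sleep duration (hours).  Activity, medicine, mood and sleep are mandatory;
  the rest may be blank.
* **clinical_ratings.csv** — one row per visit: HDRS/YMRS totals and item-1
  scores.

## Feature engineering

The 13 engineered predictors, in canonical order: activity, alcohol,
anxiety, irritability, cognitive, medicine_omitted, medicine_changed,
mixed_mood, mood_negative, mood_positive, sleep_negative, sleep_positive,
stress.

* **Mood split.** `mood_negative = min(mood, 0)`, `mood_positive =
  max(mood, 0)`: depressed and elevated mood get independent weights,
  since each is expected to track a different scale.
* **Sleep split.** Sleep is centred on the subject's mean — computed on
  training rows only, so held-out visits never influence a training
  feature; subjects absent from training fall back to the population
  training mean — and split by sign the same way.  Both deviations from
  habitual sleep directions can signal deterioration.
* **Medicine.** Dummy coded with "taken as prescribed" as the reference
  level (no column), avoiding the dummy-variable trap.
* **Normalization.** Each component is divided by its allowed extreme:
  signed items by 3, alcohol by 10, 0–2 items by 2, binaries untouched.
  Sleep deviations have no hard bound; they are divided by 12 h and
  clipped to [−1, 1] (configurable).  The signed max-abs convention keeps
  the natural zero anchor, so the intercept reads as severity at a
  neutral self-report.

A rating is valid on the visit day and the three preceding days
("back-fill"), giving up to four day-level target rows per visit.  If two
validity windows overlap, a day goes to the nearest visit (later visit on
a tie; with backward-only windows the tie cannot actually occur, but the
rule is implemented).  Rows with any missing included item are dropped —
complete-case analysis, no imputation.  Duplicate same-day entries keep
the last record.

## Hierarchical model and priors

```
alpha_j, beta_j ~ Normal(mu, diag(tau)^2)
y_ji           ~ Normal(alpha_j + beta_j' x_ji, sigma)
```

`tau` is a per-weight SD (diagonal population covariance), so each
predictor has its own degree of pooling.  Hyperpriors are weakly
informative defaults, exposed in `PriorSpec`: `mu_k ~ Normal(0, 10)` for
the intercept and `Normal(0, 5)` for weights (features live in [−1, 1]
and totals in 0–52/0–60, so these are diffuse), `tau_k ~ HalfNormal(5)`,
`sigma ~ HalfNormal(5)`.  The four targets (two totals, two item-1
scores) are fitted as independent models.  Relapse risk is the posterior
predictive exceedance probability `Pr(y~ >= T)` with `T = 13` (">=", a
total-score criterion; item-1 models are excluded from risk scoring).
Point predictions use the posterior predictive mean, computed exactly as
the posterior mean of the linear predictor.

### Sampler

No gradient-based probabilistic-programming backend is used; inference is
a blocked Gibbs sampler written for exactly this model family:

1. subject coefficient vectors: conjugate multivariate normal updates
   from per-subject sufficient statistics;
2. population means: conjugate normal updates;
3. `tau_k` and `sigma`: univariate slice sampling on the log scale
   (half-normal priors are not conjugate);
4. an ancillarity–sufficiency interweaving step: `(mu, tau)` are redrawn
   jointly in the non-centered parameterization `theta_j = mu + tau∘e_j`,
   where both are linear-regression coefficients with an exact conjugate
   conditional.  The sign of `tau` is unidentified there; folding it onto
   `tau >= 0` (flipping `e` accordingly) leaves the half-normal prior
   invariant.  Without this step the centered kernel mixes very slowly
   when `tau` is small; with it, bulk ESS exceeds 100 and R-hat stays at
   or below ~1.03 at 2 chains × (500 warmup + 1000 draws).

Chains start from jittered pooled least-squares estimates; R-hat and bulk
ESS per parameter come from ArviZ, and fits warn when R-hat > 1.05 or
ESS < 100.  Numerical floors: `tau >= 1e-10`, `sigma >= 1e-5` and a
residual-sum floor of `1e-9` keep the kernel proper on degenerate
(zero-residual) inputs.  A constant feature column makes the design
singular and is rejected by name.  Fixed seeds reproduce draws exactly.

## Baselines

Pooled/separate naive means, ridge regression (scikit-learn) and
XGBoost regression, all consuming the identical engineered features.
Hyperparameters are fixed, not tuned: ridge penalty 1.0 (on normalized
features), 100 boosting rounds at depth 3 and learning rate 0.1.  A
separate regression for a subject with fewer rows than features falls
back to that subject's mean (the fit is ill posed); unseen subjects fall
back to the pooled training mean.

## Evaluation

Cross-validation holds out one uniformly chosen clinical evaluation per
subject per iteration — the visit's whole validity window (≤ 4 rows)
moves together — and refits everything else, recomputing per-subject
sleep means on the training rows of each fold.  Subjects need at least
three distinct visits to be eligible.  Metrics per iteration, pooled over
subjects (held-out sets have at most 4 rows per subject, so per-subject
aggregation would be unstable): predicted `R² = 1 − SSE/Σ(y − ȳ_test)²`
with the held-out mean in the denominator (a pooled training-mean
predictor then scores about zero and worse-than-mean models go negative)
and RMSE.  Model comparisons use Welch two-sample t-tests on the
per-iteration metric values.  Variable importance is
`|t| = |posterior mean(mu_k)| / posterior SD(mu_k)` with a 95% percentile
credible interval, sorted descending.  Risk scores are evaluated as a
binary classifier (positive class: rating ≥ 13) via rank-based ROC/AUC;
the mean baselines produce degenerate binary scores, so their step-like
ROC curves and chance-level pooled-mean AUC are expected, not bugs.

## Synthetic cohort generator

Defaults are the study conditions the pipeline is designed for: 84
subjects, 270 days, 5 visits at protocol-like spacing (~ baseline, 4
weeks, 3/6/9 months, with ±2-day jitter), 30% of daily entries missing
(≈ 190 completed entries per subject), optional items additionally blank
3% of the time.  Ground-truth population weights and per-weight SDs
default to the published cohort estimates for the HDRS model, and the
residual SD to the published in-sample RMSE (2.41).

Per subject, a latent affective valence follows a slowly mixing AR(1)
process (persistence 0.99 per day, so episodes last weeks to months);
items are noisy monotone maps of the valence into their declared ranges,
with iid day-level reporting noise (SD 0.5 by default).  Medicine
adherence and mixed mood come from persistent latent states rather than
daily coin flips.  Sleep is reported on a half-hour grid around a
subject-specific habitual mean (7 ± 0.7 h).  On visit days the engineered
features of that day (sleep centred on the subject's true mean) feed the
linear model; the depression total is drawn, rounded and clipped to scale
bounds (rounding/clipping can be disabled for recovery diagnostics).  The
mania total uses a deterministic mirror of the same weights — the
negative/positive mood and sleep weights negated and swapped — so
elevated mood raises the mania score; item-1 scores are derived fractions
of the totals, capped at 4 and at the total.  Everything is deterministic
given the seed.

What the generator does *not* emulate: informative missingness (days are
dropped at random, whereas real patients plausibly skip entries when
unwell), item marginals calibrated to a real cohort (only ranges and
qualitative shape), rater effects, and any feedback from ratings to
behaviour.  Passing tests therefore demonstrate correctness of the
machinery and qualitative behaviour under a realistic data shape, not
clinical performance.

## Simulation studies and design choices

* **Parameter recovery** (`experiments.recovery_study`): 20 cohorts of 40
  subjects × 100 days × 5 visits, residual SD 2, clipping disabled.
  Recovery is scored on visit-day rows (back-fill window 0).  Rationale:
  back-filling duplicates one rating across up to four near-identical
  rows, which over-counts likelihood information — a structural feature
  of the real data pipeline, not a recovery testbed; on visit-day rows
  the generative and analysis models coincide exactly, so posterior
  z-scores and 95% CI coverage are well-posed.  The full-window behaviour
  is exercised by the ordering study.
* **Model ordering** (`experiments.ordering_study`): one 40-subject
  cohort with heterogeneous subjects, K = 20 hold-one-visit-out
  iterations (scaled down from K = 100 to keep a laptop run in minutes;
  the ordering is stable well before that), hierarchical vs pooled and
  separate means, with relapse-risk AUCs pooled across iterations.
* Sampler budgets in the studies (2 chains, 300–400 warmup, 300–400
  draws) are sized for study runtime; single production fits default to
  4 chains × (500 + 500).

## Known limitations

* Days are modelled independently; no forecasting ahead of the last
  self-assessment.
* The four back-filled rows of one visit share a single rating, so the
  likelihood treats correlated rows as independent; in-sample residual
  SDs are accordingly optimistic.
* Complete-case filtering assumes data missing at random.
* The Gibbs sampler is specific to the normal linear hierarchy with a
  diagonal population covariance; correlated population covariance or
  non-normal likelihoods would need a different kernel.
* Item-1 targets are supported throughout fitting/CV but excluded from
  risk scoring by design.
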