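# Methods

## Problem and design

`tweetfx` estimates the causal effect of an organization's weekly tweet
sentiment polarity on engagement under a quasi-experimental design. Because
polarity is not randomized — busier accounts, weeks with higher caseloads,
and different organization types all shift both the tone and the audience
response — the comparison of positive (SP=1) and negative (SP=0)
account-weeks is adjusted by inverse probability weighting on a logistic
balancing score.

The identification assumptions are the usual ones for IPW: no unmeasured
confounding given the eight covariates (NT, LT, MF, NI, HF, CC, ND, OG),
positivity within the trimmed score band, and well-defined treatment per
account-week. None of these are testable from the data; the package's
diagnostics (score-overlap plots, standardized mean differences before and
after weighting, trimming counts) only show whether the *measured*
covariates are balanced.

## Sentiment scoring

Tweets are lowercased, URL/mention/hash-stripped, and split on
non-alphanumeric runs. A signed seed lexicon (AFINN dialect: integer scores
−5…5, TSV input) labels each document by the sign of its summed score.
Tokens of positive- and negative-seeded documents form two reference
corpora, and each term is scored by the smoothed log2 odds ratio

    Score(w) = log2[(freq(w,pos)+α)(freq(neg)+α) / ((freq(w,neg)+α)(freq(pos)+α))]

with `freq(pos)`/`freq(neg)` the total token counts of the corpora. The
weekly score SS sums `Score(w)` over the week's token stream with
multiplicity; SP = 1(SS > 0), and SS = 0 weeks are excluded from estimation
(they are retained in the weekly table with an "excluded" marker).

Choices made where the procedure was underdetermined:

* **Pseudocount α = 0.5** (Haldane) on all four counts, because the raw
  odds ratio is undefined for terms unseen in one corpus. α = 0 reproduces
  the unsmoothed formula exactly and is exercised by the tests.
* **Reference corpora are bootstrapped from lexicon seed labels** at the
  document level; a pure-lexicon mode (`sentiment_mode: lexicon_only`,
  SS = summed lexicon scores) is available as a fallback and sensitivity
  check.
* `freq(pos)` is read as the **total token count** of the positive corpus
  (not a per-term quantity); scores come from one global corpus, not
  per-account corpora.

## Aggregation conventions

Weeks run Sunday 00:00 UTC to the next Sunday 00:00 UTC (half-open);
the keyword topic filter is case-insensitive substring matching (this
deliberately admits false positives such as "corona beer"); LT counts
characters of the raw text; MF/HF are the median/maximum of distinct-term
counts pooled over the week; account-weeks without tweets are zero-filled so
the account × week grid is complete; response rates are weekly totals
divided by NT. Responses are attributed to the tweet's own week, whenever
they actually arrived.

## Balancing score and estimators

SP is regressed on the eight covariates (plus intercept) by maximum
likelihood logistic regression (statsmodels `Logit`). Covariates enter
untransformed; they are standardized internally only, for numerical
stability, and coefficients are mapped back to the original scale. Constant
covariates (e.g. OG inside a single-type slice) are dropped from the fit
and reported with coefficient 0. If the fit does not converge or any
standardized coefficient exceeds 15 in magnitude — quasi-separation, which
is likely when the score distributions of the two groups barely overlap —
the model is refit with a small ridge penalty (1e−4 on standardized slopes)
and flagged; coefficients are treated as nuisance parameters throughout,
never as substantive estimates. Fitted scores are clipped to
(1e−12, 1−1e−12).

Weights are `1/p` (treated) and `1/(1−p)` (control). Trimming defaults to
excluding units with `p` outside [0.3, 0.7]; the alternative `cap` mode
instead truncates weights to the implied closed interval [1/0.7, 1/0.3] ≈
[1.43, 3.33]. Trimming is applied after the balancing fit, before
estimation.

Two weighted estimators are reported alongside the unadjusted difference of
means:

* `ipw_ht`: the 1/n (Horvitz–Thompson) form, with n the untrimmed count —
  the design's printed estimator and the default;
* `ipw_hajek`: group-normalized weights. Provided because the 1/n form is
  not invariant to adding a constant to the outcome, and because at a few
  hundred units the 1/n form with *estimated* scores shows a small
  finite-sample overshoot (a few percent of the effect) with heavier-tailed
  replicate distributions, while the Hájek form is effectively unbiased.
  Both are computed by every fit; simulations with true scores confirm the
  1/n form itself is unbiased.

The group comparison t-test is Welch's (unequal variances), two-sided, on
the unweighted groups. Uncertainty for every estimator comes from a
nonparametric bootstrap: account-weeks are resampled i.i.d. with
replacement (non-stratified), the entire chain (balancing fit → weights →
trimming → estimate) is re-run per replicate, and the replicate SD and
2.5/97.5 percentile interval are reported. Replicates in which a group
empties before or after trimming are redrawn and counted; estimation aborts
if redraws dominate (50× the replicate budget).

Dataset slices (pooled, government-only, news-only) re-fit the balancing
score within the slice.

## Synthetic data generator

The generator emulates the study conditions: 9 accounts (5 government, 4
news) × 24 weeks = 216 account-weeks, with defaults chosen once from the
study's published summary statistics:

* **NT** negative binomial, account-specific activity (lognormal σ = 0.6
  around a mean of 70 tweets/week), dispersion k = 5; the first two weeks
  are scaled by 0.005 so most early account-weeks have no topic tweets —
  reproducing the real dataset's zero-score rows that are excluded before
  estimation.
* **LT, NI** proportional to NT (≈80 characters and ≈12 tokens per tweet,
  Gaussian noise); **MF** ≈ 1 with rare bumps; **HF** ≈ 0.85·NT with
  lognormal noise, clamped to [MF, NI].
* **CC/ND** deterministic logistic growth per region (peaks 6×10⁵, 1.2×10⁵,
  3.5×10⁴, 2.5×10³ weekly cases for the four regions; onset weeks 17, 17,
  9, 15; deaths 6% of cases, lagged one week; "worldwide" sums the
  regions), matching the magnitude and two-wave timing of the study period.
* **Assignment** SP ~ Bernoulli(logistic(γ′Xs)) on within-dataset
  standardized covariates, γ = (1, 0, 0, 0, 0.8, 0.8, 0.5, −0.5): positive
  polarity is more likely in high-activity, high-caseload weeks and less
  likely for news agencies, which confounds naive comparisons in the
  direction observed in practice (raw contrasts attenuated toward zero).
* **Outcomes** Y = NB(mean = intercept + b′Xs + τ·SP, k = 5), truncated at
  zero (truncation is negligible at the default scales); intercepts
  150/1500/800 and τ = (−70, −690, −325) for RP/FV/RT echo the magnitudes
  of the motivating analysis. Outcome loadings share signs with γ.
* **Tweet-level corpora**: each active week emits NT tweets whose tokens are
  drawn 85%/15% from sign-matched halves of a synthetic signed lexicon
  (plus a topic keyword so the filter keeps them, and occasional off-topic
  decoys that it must drop); weekly engagement totals are split
  multinomially across tweets. The intended weekly polarity is recoverable
  by the sentiment module with ~100% accuracy at default sizes.

Ground truth (true assignment probabilities, realized SP, τ) is returned as
a separate object and serialized to a sidecar JSON so estimators cannot
read it. What the generator does **not** emulate: real linguistic structure
(token bags only), response lag across weeks, serial correlation within
accounts beyond the fixed activity level, and block-specific effect
heterogeneity. Passing tests therefore certify the estimation machinery,
not robustness to those real-data features.

## Numerical and degenerate-input conventions

Boundary balancing scores equal to a trim bound are kept (closed band).
Zero pooled SD makes a covariate's SMD 0 with a `degenerate` flag. A t-test
on two identical constant groups reports (t, p) = (0, 1). Bootstrap SD uses
ddof = 1. All randomness flows through `numpy.random.default_rng` seeds;
identical configuration and seed give byte-identical serialized outputs.

## Problem sizes used in checks

The verification suite works at the study scale (216-row grids): effect
recovery averages 200 replicate datasets, null calibration 500, bootstrap
coverage 100 datasets × 500 replicates, and oracle agreement uses 1,000
small random instances (IPW sums, 1e−12) and iteratively refined likelihood
grid searches (balancing fit, 1e−4). The pipeline tests use a smaller
6-account × 16-week corpus, the smallest configuration at which per-slice
bootstrap estimation is reliably well-posed.

## Known limitations

* The balancing model is the analyst's to specify; only the eight study
  covariates are built in, untransformed, although `PolarityEffectModel`
  accepts any covariate list.
* No closed-form/sandwich IPW variance; bootstrap only.
* No doubly-robust, matching, or difference-in-differences estimators, no
  block-effect or time-trend modelling.
* The excluded-unit rule (SS exactly 0) is knife-edge by construction;
  corpora whose scores cancel exactly are excluded rather than tie-broken.
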