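# Methods

## The prediction problem

A donor's pre-donation capillary haemoglobin (g/L) decides whether they may
donate: below 135 g/L (men) / 125 g/L (women) the attempt becomes a low-Hb
deferral. Donation histories are short, irregular longitudinal series, and
most of the predictable variation is donor-level: some donors simply run
low. The package predicts each donor's *next* (held-out last) donation from
the earlier ones and converts the prediction into a deferral probability.

## Linear mixed models

For donor *i* at donation *t*,

    y_it = x_it'β + c_i'φ + b_i + ε_it,
    b_i ~ N(0, σ_b²),  ε_it ~ N(0, σ_ε²),

with donation-varying covariates x_it (age, warm season April–September,
days since previous attempt, lifetime donation count, and — in the dynamic
variant, DLMM — the previous Hb), donor-constant covariates c_i (height,
weight, smoking, SNP minor-allele dosage, polygenic score), and a donor
random intercept b_i. Continuous covariates are standardized with
training-row statistics only; binary covariates stay 0/1.

**Inference.** Full conjugacy: Normal(0, 10²) priors on all coefficients
(standardized scale) and Inverse-Gamma(2, 1) on both variances, sampled by
a blocked Gibbs sampler — (all coefficients | b, σ) as one multivariate
normal block via Cholesky, (b | rest) as independent normals using
per-donor residual sums, and each variance as an Inverse-Gamma draw.
Defaults are 4 chains × 1,000 post-warmup draws (pipeline runs use 2 × 400,
which suffices at desk scale); convergence is rank-normalized split R-hat
< 1.05 per parameter, reported as a diagnostics flag rather than an
exception. Per-variable prior-SD overrides allow pinning a coefficient at
(effectively) zero, which nests the static LMM inside the DLMM and is used
by the test suite.

Correctness is checked two independent ways: against the closed-form
conjugate posterior of the collapsed model (random intercepts and
coefficients integrated analytically, variances fixed) on a tiny dataset,
and against an exact grid posterior over (σ_b, σ_ε) with the intercepts
collapsed by Woodbury identities. A 100-replicate simulation study (1,000
donors × 7 events) verifies ≈95% coverage of the 95% HPDIs for every
coefficient.

**Prediction.** For a test donation the posterior-predictive mean over
draws of x'β + c'φ + b_i is the Hb prediction, and the deferral probability
is the draw-averaged Φ((limit − μ)/σ_ε). Test donors always have fitted
intercepts because each donor's earlier events are in the training rows; if
a caller removes donors from training (the enrichment experiment does), the
intercept can instead be integrated out (predictive SD √(σ_ε² + σ_b²)).

**Effect sizes.** For comparability across binary and continuous
predictors, continuous coefficients are reported on the 2-SD scale (raw
coefficient × 2 SD of the raw variable) with 95% HPDIs; binary coefficients
are left as they are.

## Baseline and random forest

The baseline is a maximum-likelihood logistic regression of deferral on the
previous Hb alone, fitted per sex; complete separation or one-class labels
fall back to an L2-penalized fit with a warning flag. Because it is
monotone in a single predictor, its optimal probability cutoffs correspond
to plain Hb thresholds.

The random forest is one joint model for both sexes (sex is a feature),
over per-event rows carrying the previous Hb and the lifetime donation
count (first events, which lack a lag, are excluded). Deferral rarity is
handled by a donor-level balanced bootstrap: donors are resampled with
replacement so that in expectation half of the sampled donors have a
deferral as their last event, every event of a sampled donor entering
together. The forest (scikit-learn, 300 trees) is trained on that bootstrap
— each tree then row-bootstraps the balanced sample, so tree-level training
sets are themselves balanced draws. Hyperparameters (features per split ×
minimum leaf size, 9 combinations) are chosen by donor-grouped 4-fold
cross-validation maximizing AUROC on the natural-composition held-out
folds; no donor's rows ever cross a fold boundary.

## Evaluation

RMSE/MAE for Hb; AUROC (Mann–Whitney, tie midranks), AUPR (step
integration) and deferral-class F1 for classification, all verified against
brute-force enumerations on small inputs. Uncertainty is a percentile
bootstrap resampling donors (test sets hold one row per donor; donor-level
resampling stays correct if that changes); ranking-metric replicates with
one class are skipped, and more than 20% skips is an error.

## Economics of personalized intervals

Flagged donors (predicted positive at the cutoff, plus all observed
deferrals) get their interval extended to 183 or 365 days. Per donor the
multiplier is a_i = max(1, prolongation / baseline interval) with the
donor's mean historical gap as the baseline (sex minimum interval — 61 d
men / 91 d women — as fallback); a_tot is the donor mean of a_i and q the
classifier's deferral-class sensitivity. The per-donation effect is

    E = P_M·[(F/F_adj − 1) − (1 − F_new)·d·q·r_loss] − P_D·d·q,
    F_adj = (F − F_new)/a_tot + F_new,

with defaults P_M = 2.287 €, P_D = 20.342 €, d = 0.032, F = 1,
F_new = 0.107, r_loss = 0.167. Only returning donors (F − F_new) are scaled
by a_tot: new donors do not yet have personalized intervals. The influx
formula is stated ambiguously in some sources ("F − F_new/a_tot + F_new");
the returning-donor reading adopted here is the one consistent with its own
prose and with the ≈ −0.1 €/donation result at (a_tot = 1.12, q = 0.51) —
the left-to-right reading is off by roughly 3×. E is linear and strictly
decreasing in q, increasing in a_tot, and the break-even sensitivity has
the closed form q* = P_M·(F/F_adj − 1) / (d·[P_M·(1 − F_new)·r_loss + P_D]);
beyond a_tot ≈ 1.33 (default parameters) q* exceeds 1 and no classifier
breaks even. The threshold scan walks cutoffs 0.02 … 0.98 (step 0.02) and
picks the minimal E, ties going to the smaller cutoff (flags more donors —
the donor-health-conservative choice).

q counts only *predicted* positives as avoided deferrals even though
observed deferrals are also flagged for the interval extension: the
observed deferral has already happened and cannot be avoided, it can only
be prevented from recurring — which the a_tot side of the model prices.
a_tot is averaged over donors (not donations); the alternative convention
would weight frequent donors more heavily.

## The synthetic cohort generator

Hb is generated as baseline(sex) + b_i + effects + d_it where d_it follows
a first-order autoregression (coefficient 0.45) whose innovations have SD
6.5 g/L, the first deviation drawn from the stationary distribution;
b_i ~ N(0, 6²). Effects: −1.5 g/L in April–September, −0.8 g/L per decade
of age over 40, +0.5 g/L per 100 days of gap beyond the sex minimum
interval, −8 g/L per minor allele of a SNP carried by ~2% of donors
(Hardy–Weinberg dosage), and sex baselines 154.5 / 143.0 g/L (men/women,
57% women). These defaults were calibrated once so that the overall
simulated deferral rate at the 135/125 g/L limits lands at ≈3.2%
(3.07–3.25% across seeds at 20,000 donors). Series lengths are shifted
geometric (p = 0.12, mean ≈ 8), matching the exponential tail of real
donation-count distributions. Gaps are the sex minimum interval plus an
exponential extra (mean 60 d) after a full donation; a deferred attempt
draws no blood and is followed by a shorter re-attempt delay (30 d plus an
exponential with 30 d mean). Hb values are rounded to whole g/L as
point-of-care devices report them.

What the generator does *not* emulate: iron kinetics and ferritin recovery,
menstruation/diet/health covariates, measurement error structure of
capillary devices beyond rounding, seasonal donation-frequency patterns,
multi-site effects, and donor dropout correlated with deferral. Passing
tests therefore demonstrate that the estimators recover the structure they
assume and that the pipeline's plumbing is correct — not that the models
attain any particular accuracy on real registry data, where reported
metrics depend on confidential cohorts. In particular the near-parity of
baseline, DLMM and forest AUROCs holds here because (as in real data) the
dominant signal is the donor's own Hb level, which all three models access
through the previous Hb and/or the random intercept.

## Numerical and design notes

- Deferral boundary: deferred iff Hb strictly below the limit; a measurement
  exactly at 125/135 g/L is an acceptance (limits are acceptance
  thresholds).
- Hb plausibility range (25, 250) g/L, configurable; cleaning drops (never
  imputes) rows with missing Hb/sex/date, implausible Hb, or out-of-order
  within-donor dates, and is idempotent.
- Constant design columns (e.g. an unobserved SNP in a small stratum) are
  dropped with a warning rather than failing the rank check; genuine
  collinearity (duplicated information) is an error naming the columns.
- Desk-scale defaults: pipeline cohorts of 2,000 donors, 2 chains × 400
  draws, 200 bootstrap replicates, 300 trees — chosen so a full run of all
  four models with both prolongations completes in a few minutes on one
  core while leaving every qualitative conclusion unchanged at larger
  sizes.
- Seeds: every stochastic step takes an explicit seed; the pipeline derives
  per-stage seeds from one global seed via `numpy.random.SeedSequence`.

## Known limitations

- The Gibbs sampler mixes slowly when σ_b is near zero (a known property of
  unblocked variance-component samplers); the exact-posterior oracle in the
  test suite bounds the error at the scale tested.
- The forest's oversampling implements the one-shot donor-balanced
  bootstrap; a literal per-tree resampling scheme would require a custom
  ensemble loop and is approximated by the trees' own row bootstraps of the
  balanced sample.
- The economic model assumes marketing response proportional to budget and
  prices all deferrals identically; it is a first-order screening tool, not
  a forecasting model.
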