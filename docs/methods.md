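# Methods

## Model

The response is binary and modelled through the logistic link:
logit(P(Y=1|x)) = α + c·x. Predictors are numeric-coded categorical
columns; text columns are coded by sorted-level integer assignment and
categoricals with more than two levels are expanded to reference-coded
indicator columns (reference = first level in sorted order), so every
column carries exactly one coefficient and one odds ratio. Fits are
maximum likelihood via Newton's method (statsmodels). When separation
or non-convergence is detected, the fit is repeated with an L2 penalty
of strength 1e-6 on the slopes (intercept unpenalised) and flagged;
this magnitude perturbs well-posed problems far below reporting
precision while taming separation. Standard errors then come from the
penalised Hessian.

## The CARS selection loop

At run i of N (default N = 50):

1. sample ⌊0.8·s⌋ rows without replacement;
2. fit the logistic model on the current survivors;
3. weight each survivor by h_i = |c_i| / Σ|c_j|;
4. keep the top-weight variables down to the EDF count
   n_i = max(2, round(q_i·v)), q_i = z·e^(−t·i),
   z = (v/2)^(1/(N−1)), t = ln(v/2)/(N−1) — round-half-up, so the
   endpoint counts v and 2 are honoured exactly;
5. draw n_i weight-proportional samples with replacement from the kept
   pool; the distinct drawn set survives to the next run;
6. score that set by stratified 10-fold cross-validated held-out
   deviance (mean negative log-likelihood per observation) on the full
   dataset, so scores are comparable across runs.

The minimum-score run wins; its set is refit on all rows. The
significance threshold of 0.05 is applied, by default, as a final-model
Wald prune (variables with p ≥ 0.05 are dropped and the model refit).
A normalized-weight cutoff cannot be the early-run rule: mean weight is
1/v, so for v > 40 a 0.05 weight cutoff would annihilate the pool and
contradict the q₁ = 1 condition. A per-run weight-cutoff mode
(`threshold_mode="weight"`, retaining at least the top two) is provided
for users who read the threshold that way; the prune never empties the
winning set (if every variable would drop, the unpruned set is kept).

Randomness: one master seed spawns an independent substream per run
(row sampling, ARS draws, fold shuffling), so increasing N leaves
earlier runs unchanged and the whole procedure is a pure function of
(dataset, configuration, seed). Ties in forced elimination keep the
lower column index; ties in winner selection keep the earlier run.

## Baseline and assessment

Forward selection starts from the intercept-only model and greedily
adds the column with the largest AIC decrease, stopping when no
addition decreases AIC (an entry-p-value mode, default threshold 0.05,
is available). Both methods return the same result shape.

Five criteria are computed from log-likelihoods only, with k counting
all estimated parameters including the intercept:
AIC = 2k − 2ℓ̂; BIC = k·ln n − 2ℓ̂; McFadden R² = 1 − ℓ̂/ℓ₀;
adjusted McFadden R² = 1 − (ℓ̂ − k)/ℓ₀;
Cox & Snell R² = 1 − exp(2(ℓ₀ − ℓ̂)/n).

The comparison harness preprocesses once, hands both arms byte-identical
input, selects on a stratified 70% training split and computes the five
criteria from held-out log-likelihood on the 30% test split (the null
likelihood uses the training event rate). This is deliberate: in-sample,
AIC-greedy forward selection reaches lower in-sample AIC than any more
parsimonious subset by construction, so an in-sample comparison would
measure nothing but model size. Held-out assessment rewards selections
that generalise. Setting `test_fraction=0` recovers the in-sample
comparison. Subset overlap is reported as a Jaccard percentage,
100·|A∩B|/|A∪B| (the convention is echoed in the output metadata).

## Preprocessing

Order: near-zero variance → outliers → correlation.

- **NZV**: drop columns with most-common/second-most-common frequency
  ratio > 19 (i.e. 95:5) AND distinct-value percentage < 10; constant
  columns always drop. These are the dominant conventional thresholds.
- **Outliers**: drop rows whose Pearson residual (y−p̂)/√(p̂(1−p̂)) from
  the full-model fit exceeds 3 in absolute value; abort if more than
  20% of rows would drop (that pattern indicates misspecification).
  If the full design is exactly aliased (e.g. duplicate columns that
  the later correlation filter will remove), the fit uses a maximal
  linearly independent column subset — residuals are invariant to the
  basis of the column space.
- **Correlation**: while any |Pearson r| > 0.7 remains, drop the member
  of the worst pair with the larger mean absolute correlation against
  all other survivors (ties keep the lower column index). Deterministic
  given column order, and idempotent.
- **Binned residuals**: rows sorted by fitted probability are split
  into ⌊√s⌋ near-equal bins; each bin reports the mean raw residual and
  a two-sided 90% normal band of half-width 1.6449·sd/√(bin size). The
  fraction of bins inside the band summarises residual independence.

Pearson correlation on coded columns (rather than a categorical
association measure such as Cramér's V) is the package's choice; for
0/1 columns the two coincide up to sign.

## Synthetic data

The generator emulates a survey-style screening problem: v independent
Bernoulli predictors with per-column success probabilities drawn
uniformly from (0.2, 0.8), and a Bernoulli response through the
logistic link. With no planted effects the response is independent of
every predictor (null scenario); otherwise a chosen index set carries
chosen log-odds effects, and that set is returned as ground truth so
selection accuracy is measurable. The intercept of planted scenarios is
centred at −(Σβ)/2 to keep classes near balance. The recovery scenario
used throughout testing is n = 2000, v = 50, five unit effects; the
paper-scale fixture is n = 5000, v = 100 with a stratified 70:30 split.

What the generator does **not** emulate: correlated predictors,
multi-level categoricals, survey weights, missingness, rare outcomes.
Passing recovery tests therefore demonstrate the selection machinery on
clean independent binary designs, not performance on real survey
extracts. Note also that marginal 2×2-table odds ratios understate the
planted conditional effects when several effects are present
(non-collapsibility of the logistic model); generator checks use a
single-effect design or conditional fits.

## Numerical choices

- Fitted probabilities are clipped to [1e−12, 1−1e−12] before taking
  logs in deviance computations.
- The logistic function is evaluated via `scipy.special.expit`, which
  saturates exactly to 0/1 for extreme linear predictors instead of
  overflowing.
- Stratified cross-validation folds require the minority class to have
  at least k members; an interleaved (round-robin after sorting by
  response) fold mode is available as a deterministic alternative.
- Degenerate inputs are rejected with named diagnostics: single-class
  response, rank-deficient designs (aliased columns are listed),
  all-zero weight vectors, schedules with v < 3.

## Problem sizes

The test suite and the reproduction script run the recovery scenario at
n = 2000, v = 50 with N = 50 runs and 10-fold cross-validation — 20
seeded replicates in the test suite, 10 in `scripts/acceptance.py` —
which this implementation completes in a few minutes on a single core.
Larger problems scale roughly as N × (k_folds + 1) logistic fits.

## Known limitations

- No survey-design variance (weights, strata, clusters): estimates
  treat rows as i.i.d.
- No Firth correction; quasi-separation falls back to a small ridge
  penalty rather than a bias-reduced fit.
- The ARS draw count equals the EDF keep count of the same run; the
  realized subset can be smaller (that shrinkage is the competitive
  step), but no separate draw-count control is exposed.
- Forward selection is strictly forward; no backward or bidirectional
  stepwise variants.
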