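# Methods

`c3b` implements the computational core of a two-module self-administered
cognitive screening battery: test scoring, regression-based demographic
norms, screening classification with signal-detection diagnostics, and
test-retest reliability statistics. Everything downstream of scoring is
validated on synthetic cohorts whose generating truth is known, because no
subject-level normative data are distributed.

## Test scoring

**Visual Memory Test (VMT).** A stimulus is 7 symbols — one from each of 7
semantic categories, 6 exemplars per category (42 symbols total) — placed on
7 cells of a 4×6 board, the cells taken from one of 6 location patterns.
The canonical patterns are not published; the package ships 6 fixed patterns
chosen so that no two share more than 3 cells, which preserves the design
intent (displays that are hard to confuse across administrations). Scoring
per trial: each of the 7 target cells earns 2 points if it holds its correct
symbol, 1 point if it holds any other symbol, 0 if empty; maximum 14. A
correct symbol on a non-target cell earns nothing — the published rule is
location-centric ("one point if the patient places any symbol in one of the
7 squares"), and we follow that reading. Sessions run 5 trials; after two
consecutive 14s the test discontinues and the remaining trials are allotted
14 (maximum 70). A session shorter than 5 trials that never triggered the
discontinue rule is rejected as incomplete rather than given a partial
total. Grid coordinates are 1-based `(row 1–4, col 1–6)` everywhere,
including the JSON session schema.

**Processing Speed Test (PST).** A key maps 9 symbols (drawn without
replacement from a 30-symbol pool) to a permutation of the digits 1–9.
Responses are a stream of presses aligned one-to-one with presented items
(the task advances automatically, so items cannot be skipped). A press is
scored iff its timestamp is ≤ 120 s — a closed boundary, so a press exactly
at 120 s counts — and is correct iff the digit matches the key. Symbols are
abstract identifiers; no artwork is rendered.

## Regression-based norms

Each test's normative model is an ordinary least-squares regression of the
raw score on demographics:

- PST: `intercept + β_age·age + β_nl·(age − 50.26714)² + β_edu·educ +
  β_sex·sex + β_race·race`, RMSE 8.958;
- VMT: `intercept + β_age·age + β_nl·max(0, age − 71)² + β_edu·educ +
  β_race·race` (no sex term), RMSE 12.879.

The quadratic spline term activates only above the age-71 knot, so the VMT
prediction is continuous and once-differentiable there. Note that the PST's
*linear* age term is uncentered: at the centering age only the quadratic
term vanishes. Indicator coding is male=1/female=0, African-American=1/
non-AA=0 (negative coefficients encode the observed male and AA
disadvantages); education enters as raw years. The adjusted z-score is
`(raw − predicted) / RMSE`, where RMSE is the residual SD with denominator
n − p — the same quantity the fitter reports, so refit models plug into the
z formula unchanged. Demographics outside the normative age range (18–89)
produce a warning and an `extrapolated` flag rather than an error: clinical
callers need the number with a caveat, not a refusal.

Fitting goes through `statsmodels` OLS on explicitly constructed design
matrices. Rank deficiency raises an error naming the offending columns
(found by a left-to-right rank scan). `select_model` fits a set of candidate
bases (linear age, centered quadratic, knot-71 spline) and keeps the highest
adjusted R², breaking ties toward fewer coefficients — the same criterion
used to settle the published forms.

The shipped coefficient file (`data/coefficients.json`) carries the
published sets verbatim under the identifier `c3b-published-norms-v1`; every
report embeds that identifier, the tool version and the seed.

## Screening

Impairment uses the minimum of the two z-scores with a strict inequality
(`min(z_pst, z_vmt) < −0.4` by default), because an MCI patient may be
deficient in memory, speed, or both. A subject with one missing z is
classified on the available score (listwise exclusion is available to
callers; unscorable counts are always reported). Diagnostics are the
standard 2×2 quantities: sensitivity tp/(tp+fn), specificity tn/(tn+fp),
Youden's J = sens + spec − 1. The ROC uses the discriminant −min z (larger
= more impaired); the curve comes from `scikit-learn` with no intermediate
points dropped and the AUC by trapezoidal integration, which the test suite
verifies against a brute-force pairwise P(case > control) + ½P(tie) oracle
on random instances. The Youden-optimal cutoff scans midpoints between
adjacent distinct observed scores plus the two open ends, breaking J ties
toward higher specificity; it provably dominates every observed threshold,
and a test checks exactly that. Group comparisons use Student's
pooled-variance t (Welch behind a flag) and pooled-SD Cohen's d with n−1
weights.

## Reliability

`paired_summary` reports the occasion-1 − occasion-2 difference, the paired
t with n−1 df, and the paired-design effect size d = mean_diff/sd_diff,
which equals t/√n identically (a property test asserts the identity). A
constant non-zero shift between occasions has zero difference variance; the
summary is returned with infinite t/d and a `degenerate` flag rather than
raising, since the direction of the shift is still meaningful. The ICC
defaults to ICC(2,1) — two-way random effects, absolute agreement, single
measurement — the standard form for test-retest agreement; ICC(3,1)
(consistency) sits behind a flag. Both are computed from the two-occasion
mean squares and cross-checked in the tests against an independent
implementation (`pingouin`). Pairs with a missing occasion are excluded
listwise and counted.

## Synthetic cohorts

**Normative cohort.** One record per stratum slot of the published
stratification — 3 age bands (18–39, 40–59, 60–89) × 3 education bands
(9–12, 13–15, 16–20 years) × 2 sexes, 428 records total — with age uniform
within its band, education uniform on integer years within its band, and
race Bernoulli(0.171) independent of stratum (only the marginal fraction is
published). Raw scores are the model's linear predictor plus Gaussian noise
with SD equal to the printed RMSE, rounded to integers and clipped to
attainable ranges (VMT 0–70; PST ≥ 0 with no upper clip, since items are
unlimited within the window). `scaled(n)` rescales strata counts by largest-
remainder rounding, preserving proportions while hitting the total exactly.

Two consequences of the integer/clipped score model are worth knowing.
First, ~12% of simulated healthy subjects hit the VMT ceiling of 70, which
deflates SD(z) to ≈0.92 and biases a refit VMT age slope toward zero; the
z-calibration and VMT round-trip recovery properties therefore hold — and
are tested — on the continuous generator (`round_scores=False`), while the
default generator is the more faithful picture of recorded data. The PST has
no ceiling, so PST coefficient recovery (the headline parameter-recovery
check, n = 5,000) is unaffected. Second, clipping shifts group means
slightly; the generator-fidelity tests compare sample means against the
censored-normal mean, not the nominal one.

**Case-control sample.** Gaussian scores per group at the published MCI/HC
means and SDs (PST 28.61/11.27 vs 44.27/8.48; VMT 26.57/14.97 vs
51.63/14.18; n = 30 per group), drawn jointly per subject with a
within-subject cross-test correlation of 0.5 — a realistic moderate value
for speed and memory measures in elderly samples; no such correlation is
published. Demographics mimic the validation sample (age ≈ 74 ± 6 in the
60–89 band, education ≈ 15.7 ± 3). Under this generator the min-z rule at
−0.4 yields long-run sensitivity ≈ 0.86 and specificity ≈ 0.70: specificity
sits below the published 0.83 because the published cutoff was optimized
in-sample on the same 30 controls it was then evaluated on, an optimism the
generator does not (and should not) reproduce. The end-to-end test asserts
consistency with the published counts within their binomial error at
n = 30, which this generator satisfies without tuning.

**Retest pairs.** Bivariate Gaussian with specified means, SDs and true
correlation (default n = 30, r = 0.8, on the PST's scale). With equal
means and SDs the true ICC(2,1) equals the correlation, giving an exact
recovery oracle.

**VMT response simulation.** Each symbol lands on its correct cell with
probability `accuracy`; missed symbols are placed by a uniformly random
injection into the remaining free cells. Under this rule a missed symbol
can land on its own cell by luck, which makes the expected trial score
available in closed form, E[2k + (7−k)(8−k)/(24−k)] over k ~
Binomial(7, accuracy) — the oracle the Monte-Carlo test checks against. An
`off_pattern` strategy forces misses onto non-target cells (accuracy 0 then
scores exactly 0).

## Problem sizes and numerical choices

Simulation-based tests use n = 2,000–10,000 where an estimator's sampling
error must be small (coefficient recovery, ICC recovery, null
distributions) and n = 30 with seed-averaging where the published study's
own scale matters. All generators take explicit integer seeds and are
bit-reproducible; nothing reads global random state. Ties in the Youden
scan break toward the higher threshold; degenerate inputs (zero variance,
empty truth classes, rank-deficient designs) raise typed errors rather than
returning NaN.

## Known limitations

- The published worked example for one patient (predicted PST 31.4 and VMT
  42.1 for a 60-year-old AA man with 10 years of education) is not exactly
  reproducible from the published coefficient table under any 0/1 coding
  (recomputation gives ≈38.9 and ≈41.7); the package follows the coefficient
  table and the stated coding, and its z-from-predicted path reproduces all
  printed z values from the printed predicted scores.
- The published retest ICCs (0.830 PST, 0.693 VMT) and real-cohort adjusted
  R² values cannot be recomputed without the raw data; the estimators are
  instead validated by parameter recovery on simulated data.
- Synthetic cohorts draw demographics independently within strata and use
  Gaussian score noise; real data show skew, floor/ceiling clustering and
  demographic-performance interactions the generator does not emulate, so
  passing tests certify the estimators, not the battery's field behavior.
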