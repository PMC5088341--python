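# Methods

## Problem and data model

The unit of analysis is one completed ecological momentary assessment
(EMA) during the first post-quit week of a smoking cessation attempt. Each
EMA carries four ordinal items coded 1–5 (urge to smoke, stress, commitment
to staying smoke free, cigarette availability; 1 = strongly disagree / not
at all available, 5 = strongly agree / easily available), two binary items
(interacting with someone smoking; alcohol within the past hour), a prompt
type (wake-anchored daily diary, random prompt, or self-initiated), and a
momentary smoking report. The roster records each participant's treatment
arm (usual care vs. contingency management), quit time, first-lapse time if
any, and a reporting-consistency flag; inconsistent reporters are excluded
from every analysis set.

## Proximity windowing

For lapsers, only EMAs strictly before the first lapse are retained; each
is labeled `WITHIN_4H` if the lapse follows within the look-ahead window
(default 4 h) and `PRE_LAPSE_OVER_4H` otherwise. All post-quit EMAs of
abstainers are retained as `ABSTAINER`. Conventions the source analysis
leaves open, fixed here:

- the boundary "exactly window-length before the lapse" counts as
  `WITHIN_4H` (window closed at both ends);
- an EMA time-stamped at the lapse instant is post-lapse — the lapse-report
  assessment is not a predictor observation;
- windows are calendar-time, not waking-time;
- records before the quit time are dropped with a logged warning.

Labeling is a partition: retained plus excluded counts always sum to the
input count, and the windowing stage logs them all.

## Risk scores

Dichotomization maps "agree/strongly agree" to ordinal ≥ 4, "disagree/
strongly disagree" to ≤ 2 under the 1–5 coding; cigarette availability is
present at ≥ 4 ("fairly easily"/"easily"). The unweighted estimator is the
count of present indicators (0–6). The weighted estimator centers each
ordinal at 3 and applies fixed coefficients (0.2 urge, 0.2 stress, 0.7
availability, 1 each binary, −0.2 motivation), treating ordinal codes as
equally spaced. Exhaustive enumeration of all 5⁴·2² = 2,500 response
profiles gives a range of [−2.6, 4.6]. The published account prints the
range as "−2.6 to 4.2", which is inconsistent with its own formula (the
all-risk profile urge=stress=5, motivation=1, availability=5, both binaries
yes evaluates to 0.4+0.4+1.4+1+1+0.4 = 4.6); this implementation follows
the formula and documents the discrepancy rather than altering either
number.

Flagging is strict (`score > cutoff`) throughout. Cut-offs stated in the
≥ convention — "3 or more factors" — are mapped to a strict threshold just
below the cut-off (`ge_cutoff(c) = c − 1e-9`); the evaluation API and CLI
expose the convention as a flag.

## Weight search

The weighting procedure is reproduced as an exhaustive Cartesian grid
search. Defaults: {0.0, 0.1, …, 1.0} for the four ordinal coefficients and
{0.0, 0.5, 1.0} for the binaries (the source describes the candidate
weights only by example, so both grids are configurable); the motivation
coefficient is constrained non-negative and always enters negatively,
matching the printed sign convention. The objective is Youden's J
maximized over all cut-offs (midpoints between adjacent observed scores;
an explicit cut-off grid can be supplied), with AUC as an alternative —
the source states only that sensitivity and specificity were maximized.
Ties are broken deterministically: smallest L1 norm of the coefficient
tuple, then lexicographic order. Because records take at most 2,500
distinct response profiles, the scan deduplicates profiles and weights
them by class counts, which keeps the full default grid (131,769
candidates) under a minute on study-sized data. As in the source analysis,
fitting and evaluation use the same records (no train/test split), so the
searched objective is optimistically biased; the planted-signal and
permutation-null tests quantify that bias at n = 5,000.

## Evaluation

AUC is the Mann–Whitney rank statistic with ties counted ½, identical to
the trapezoidal area under the empirical ROC curve (asserted to 1e-9 in
tests; curve construction delegates to scikit-learn). The 95% CI uses the
asymptotic variance of the rank statistic from DeLong's structural
components rather than a binormal fit. Two estimators scored on the same
records are compared with the correlated-ROC structural-components test; a
seeded paired bootstrap (2,000 resamples) is available as a cross-check
and agrees within 0.02 in tests. Records are treated as independent,
replicating the source analysis's disregard of within-participant
clustering; a cluster bootstrap resampling participants is provided as a
sensitivity option. Participant-level detection divides by all
consistent-reporting lapsers, including those with no EMA inside their
pre-lapse window.

Group contrasts (each factor and the count score, between proximity
classes, adjusted for treatment arm) use participant random-intercept
models: a variational-Bayes mixed logit for binary factors and a linear
mixed model for the count score. statsmodels has no exact-likelihood mixed
logit, so the logit p-values are posterior-normal approximations; whenever
a fit is degenerate or fails to converge — or a class has fewer than two
participants — the engine falls back, with a logged warning, to a seeded
permutation test (default 2,000 permutations). The permutation scheme
respects the design: contrasts that separate participants (anything vs.
abstainers) permute the participant-to-class assignment; the within-lapser
contrast (within-window vs. earlier) permutes labels within each
participant's records. The permutation route does not adjust for arm.
Under the null, the model route's type-I error is ≈5–6% over 200
replicates (tested).

## Synthetic cohort generator

The generator emulates the study conditions: 52 lapsers and 40 abstainers,
7 post-quit days, one daily diary 30 minutes after waking plus four random
prompts over a 16-hour waking window (uniform with ≥90-minute spacing,
rejection-sampled), prompt compliance 0.9, and self-initiated urge EMAs at
1.7/day — together ≈6.2 completed EMAs/day, i.e. ≈43.4 per participant
over the week, matching the reported mean of 43.5. Compliance and
self-initiation rates are not reported separately in the source; this
split is the package's own calibration to the reported total and is fixed.

Because risk-factor prevalence is known only by proximity class, items are
drawn conditional on the class an EMA will eventually occupy. Each
ordinal item's five category masses are a fixed split of the target
prevalence: positive mass 60/40 across the two indicator-positive
categories and negative mass 20/40/40 across the rest (mirrored for
motivation, whose indicator is the low end). Only the dichotomized mass
matters downstream; the split is arbitrary but fixed, and dichotomization
recovers the configured prevalence exactly in expectation. Lapse times are
uniform over the waking portions of the week, excluding the first four
waking hours so every lapser has a pre-lapse window; with probability 0.6 a
lapse-report self-initiated EMA lands within 120 minutes before the lapse.
Post-lapse EMAs (excluded from all analyses) reuse the within-window
prevalences as a plausible ambient state, and the momentary smoking report
turns true at the lapse instant. All draws descend from per-participant
substreams spawned from one master seed: identical config ⇒ byte-identical
cohort.

An optional Gaussian copula factor (one shared latent normal with loading
√ρ per item) induces positive inter-item correlation while preserving
marginals. The default is ρ = 0 (independent items), under which the
class mean factor counts are analytically 2.452 / 1.852 / 1.278
(within-window / earlier pre-lapse / abstainer), reproducing the reported
2.43 / 1.83 / 1.27, and P(count ≥ 3 | within-window) = 47.3%, reproducing
the reported 47.2% sensitivity at the count-≥3 cut-off. The independence
assumption is knowingly wrong in one respect: the reported abstainer
≥3-factor rate (11.90%) exceeds the independence prediction (8.86%),
evidence of positive inter-item correlation in the real data. That
quantity is therefore exercised through the copula knob as a sensitivity
analysis, never asserted. The generator also omits within-person
autocorrelation, diurnal structure, informative missingness, early-week
clustering of lapses, and any treatment-arm effect on lapse timing — so
passing tests demonstrate correctness of the pipeline's computations under
the stated design, not real-data effect sizes; in particular the weighted
estimator's real-data AUC advantage (0.76 vs 0.72) arises from structure
the independence generator does not encode, and is not a test target.

## Problem sizes and numerical choices

Stochastic checks use 100,000 item vectors for prevalence and mean-count
recovery (±1% and ±0.05 tolerances), 5,000 records × 20 seeds for
planted-weight recovery and permutation nulls, 200 replicates for type-I
calibration, and 2,000 resamples for bootstrap procedures. Objective ties
in the grid search are resolved at 1e-9; scores are compared with strict
inequality, and the ≥-convention epsilon is 1e-9. Timestamps are
minute-resolution ISO-8601 in a single study timezone; booleans serialize
as yes/no. Validation is total: malformed input raises a typed error
naming file, line and column — never a silent coercion.

## Known limitations

Single-lapse modeling only (as in the source analysis); no pre-quit week;
no item-level imputation (records missing any of the six items are dropped
with a logged count); the mixed-logit p-values are variational
approximations; and the permutation fallback ignores the treatment-arm
covariate.
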