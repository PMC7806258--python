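# Methods

`pseshift` implements the psychophysical analysis chain used to measure
chemosignal-induced shifts in visual gender perception under neuropeptide
manipulations, together with a generative observer model that reproduces the
factorial structure of the five experiments it analyzes. This note records
the model, the defaults and why they were chosen, the numerical decisions,
and the limits of what the synthetic data can show.

## Task and measurement model

Participants judge point-light walkers as male or female. Walker gender is
parameterized by a normalized Z score with seven equally spaced levels from
−0.45 (feminine) to +0.45 (masculine), the center having been adjusted to
each participant's approximate neutral point before the experiment. Each
block holds 70 trials (7 levels × 10 repetitions, randomized); a testing day
comprises 5 pre-administration baseline blocks (no drug, no odorant) and 7
experimental blocks under one drug × odorant combination.

Choice proportions per level are fitted with a two-parameter sigmoid. We use
the increasing logistic

    F(z; x0, s) = 1 / (1 + exp(−(z − x0)/s)),   s > 0,

so the proportion of 'male' responses rises with masculine Z; the classical
decreasing Boltzmann form f(x) = 1/(1+exp((x−x0)/ω)) is the same curve with
ω = −s. This removes a sign ambiguity that would otherwise propagate through
every shift statistic. The fitted x0 is the point of subjective equality
(PSE); the difference limen is half the interquartile range of the fitted
curve, which for the logistic is exactly s·ln 3 (asserted against numerical
inversion to 1e−10 in the tests). The PSE shift of an odorant condition is
PSE_odor − PSE_control; positive = feminine bias, negative = masculine bias.

## Baseline normalization

Response criteria wander from day to day for reasons unrelated to the
manipulations. Per level, the analysis replaces the experimental proportion
p_exp with

    p′ = p_exp − p_base + p̄_base,

where p_base is the same day's baseline proportion and p̄_base the mean
baseline proportion across the participant's testing days. Absent clipping
this is mean-preserving and cancels any additive day effect common to both
block types. The formula can leave [0, 1]; we clip and count the events
(logged per run) because the downstream least-squares fit requires valid
proportions. Clipping behavior under extreme drift is this package's choice;
out-of-range values are otherwise silently impossible to fit.

A variance accounting clarifies what normalization buys. Across days,
var(p_exp) ≈ pq/70 + (pq/s)²·σ_d² (sampling noise plus drift with SD σ_d),
while var(p′) ≈ pq/70 + (pq/50)(1 − 1/D) (the drift term replaced by
baseline sampling noise; D = number of days). At the generator's default
drift σ_d = 0.05 the exchange is favorable only at central levels; at
σ_d = 0.1 drift dominates sampling noise at every level and normalization
reduces across-day variance everywhere. The drift-cancellation tests
therefore exercise the σ_d = 0.1 regime, which is the regime the correction
exists for; the default generator keeps σ_d = 0.05, of the same order as the
condition effects.

## Generative observer model

Each synthetic participant responds 'male' at level z with probability

    P(male | z) = λ/2 + (1 − λ)·L((z − μ)/s),
    μ = true_neutral + drift(day) + Δ(drug, odor),

with lapse rate λ (default 0.02; the fitted model has no lapse term — the
mismatch is a deliberate robustness stress, not a modeling target), slope
scale s, per-day criterion drift ~ N(0, σ_d²), and a condition effect Δ
(positive = feminine bias). Carrier-control conditions have Δ = 0 by
construction.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| slope scale s | 0.15 Z (lognormal CV 0.2, clipped 0.05–0.4) | yields curves spanning the ±0.45 range without floor/ceiling saturation, matching the graded sigmoids such tasks produce; difference limen ≈ 0.165 Z |
| lapse λ | 0.02 | small keypress/attention error; bounded ≤ 0.1 |
| drift σ_d | 0.05 Z | same order as plausible condition effects — the nuisance normalization targets |
| residual neutral miscalibration | N(0, 0.05 Z) | the pre-experiment neutral setting is approximate |
| peak effect | +0.05 Z (estratetraenol, heterosexual), −0.05 Z (androstadienone, homosexual) | see effect-size calibration below |
| between-observer effect SD | 0.05 Z | idem |
| AQ | discretized N(20, 6), clipped 0–50; high-AQ cohorts ≥ 25 | population mean ~20; ≥ 25 is 1 SD above it |

**Effect-size calibration.** True shift magnitudes in Z units are not
directly observable from published statistics, so the defaults are set to
reproduce the reported effect-size scale: at the study's trial counts the
fitted-shift measurement noise is ≈ 0.04 Z per participant-condition
(measured by simulation), so a peak effect of 0.05 Z with between-observer
SD 0.05 gives a total shift SD ≈ 0.064 and a paired effect size dz ≈ 0.78
for an n = 24 subgroup — inside the 0.6–0.9 range such experiments report.
Ground-truth-injection runs used by the end-to-end pattern test configure
Δ = 0.055 (dz ≈ 0.86), chosen by a priori power analysis so that a
30-replicate check of "detected in ≥ 90% of replicates" has adequate margin
(per-replicate power ≈ 0.985).

**Dose–response model.** Condition effects follow an inverted-U in effective
oxytocin tone: gain = max(0, 1 − |tone − 12|/12), where tone is an
AQ-dependent endogenous offset (12 IU-equivalent at AQ ≤ 15, falling
linearly to 0 at AQ ≥ 25) plus any exogenous oxytocin dose. Atosiban forces
gain 0; vasopressin and saline leave tone unchanged. This reproduces the
qualitative pattern the generator must emulate — high-AQ men show no
baseline effect, a restored effect at 12 IU, none at 24 IU; low-AQ men show
a baseline effect, diminished at 12 IU, none at 24 IU; vasopressin is inert
at either dose. The knee positions are stylized: real endogenous tone is
surely not a piecewise-linear function of AQ, and within the high-AQ range
the model has no AQ gradient.

**Neutral-point calibration.** The adaptive procedure that centers the
stimulus axis per participant is not reproduced; a dedicated pre-experiment
calibration block fitted with the standard pipeline stands in for it
(`calibrate_neutral_point`), with degenerate data (all one response)
flagged and mapped to a zero offset.

**Counterbalancing.** Latin-square by default (condition order rotated
cyclically across participants; for the within-subject drug designs the two
sessions of a drug fall on consecutive days with odorant order alternated);
a random-permutation scheme is available.

## Fitting

Unweighted least squares on the 7 normalized proportions (normalization
destroys the binomial likelihood, so no likelihood is pretended; trial-count
weights are available but off by default). Initialization: x0 from linear
interpolation of the 0.5 crossing of the monotone hull, s from a quarter of
the stimulus range, expanded to a deterministic 3 × 3 multi-start grid
(x0 ± 0.1; s × {0.5, 1, 2}); bounds x0 ∈ [−1, 1], s ∈ [1e−4, 2]; ties broken
by lowest SSE, then smallest s. Constant response vectors and
boundary-pinned solutions are flagged `converged=False`, never raised;
flagged fits invalidate the affected shift, and participants with a flagged
fit are dropped pairwise from the affected comparison, with logging. The
optimizer is audited against a dense grid search (0.001 resolution on x0 ∈
[−0.5, 0.5] and s ∈ (0, 1]) on 200 random instances.

**Estimator precision.** At 70 trials per level the binomial information
bounds the PSE standard error at roughly s/√(70·Σᵢ pᵢqᵢ); for s = 0.15 this
is ≈ 0.019 Z (mean absolute error ≈ 0.015), and even an implausibly steep
observer (s = 0.06) cannot get the MAE below ≈ 0.010. Recovery is unbiased —
for the PSE, the difference limen, and injected shifts — but single-condition
PSEs carry irreducible noise of this order, which is why inference operates
on within-participant shifts across 24-participant subgroups.

## Inference

All designs are balanced and complete, so the mixed-design ANOVA is computed
by the orthogonal sum-of-squares decomposition with participants as the
within-subject error stratum: each effect is tested against the interaction
of its within-subject part with subjects-nested-in-groups. Implemented
directly with projection operators on the factorial data array; verified
against pingouin (one between × one within) and statsmodels AnovaRM (pure
within), neither of which handles the two-between × one-within and
one-between × two-within layouts this study needs. F tests are uncorrected
for sphericity (noted in output metadata); all p-values are two-sided.

Paired comparisons report Cohen's dz = mean(diff)/SD(diff) = t/√n; ANOVA
effects report partial η² = F·df1/(F·df1 + df2); both identities are
asserted on every emitted result. The quadratic dose contrast over
{0, 12, 24} IU uses scores cᵢ = xᵢ(0) − 2xᵢ(12) + xᵢ(24) with F = t²,
df (1, n−1) — the contrast-specific-error polynomial decomposition of the
one-way repeated-measures ANOVA. Within-subject error bars use Cousineau
centering with the Morey √(k/(k−1)) correction. No-drug and saline baseline
cohorts are pooled after an explicit two-sample check that is logged but
never blocks pooling (pooling is the protocol; the check is for the record).
Family-wise correction (Bonferroni or Holm) is exposed generically for
rating-scale-style families.

The bootstrap of bivariate sample means resamples participants (rows)
jointly with replacement at the full cohort size, B = 1000 by default, fully
seeded; summaries are means-of-means and 2.5/97.5 percentiles per axis —
conveniences for plotting, as the display of record is the raw scatter. The
power calculator draws paired differences from Normal(dz, 1) and reports the
two-sided rejection fraction; it is audited against the noncentral-t closed
form.

## Determinism and problem sizes

Every stochastic component takes an explicit seed (numpy Generator /
SeedSequence); identical (design, observers, seed) reproduce trial tables
byte for byte, and a full pipeline rerun with the same config reproduces all
numeric outputs byte for byte. Problem sizes used by the verification suite:
the oracle audit uses 200 instances against a ~10⁶-point grid; recovery uses
500 observers at 70 trials/level; type-I calibration uses 4000 null
replicates for the t-based statistics and 2000 for the ANOVA (MC SE ≤ 0.005
around the 0.05 level); the end-to-end pattern check runs 30 seeded
replicates of the full 72-participant between-subjects experiment.

## What the synthetic data do and do not show

The generator reproduces the factorial designs, block structure, binomial
trial noise, day-to-day criterion drift, lapses, individual differences in
neutral point, slope and susceptibility, and an AQ-dependent inverted-U
dose-response. It does not emulate sequential effects within blocks,
adaptation or fatigue within a session, non-additive drift, response-time
information, mood covariates, or any real link between AQ and behavior
beyond the stylized tone model. Passing tests therefore certify the
analysis chain — that it recovers known ground truth at the study's trial
counts and calibrates its error rates — not any property of real
participants. Headline statistics of the original study can be recomputed
only from its per-participant source data, for which the fits-level CSV
import path is provided.
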