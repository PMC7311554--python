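# Methods

## Social utility with group-dependent discounting

The package models the value of a two-party allocation option as

    U = w_own · u(own) + β · w_other · u(other)

with `u` the identity transform (a `transform` tag exists so curvature can
be added later without touching call sites, but only `identity` is
implemented). `β = 1` for ingroup partners; `0 < β < 1` discounts the
partner's payoff in outgroup settings. Weights are not normalised: only
their ratio is identified by an SVO angle, and the canonical examples use
(0.9, 0.1) and (0.5, 0.5). `β` is a free parameter (no dataset here pins
it down); the package default is 0.5.

Choice is the utility argmax; differences below 1e-9 count as ties and are
resolved by a seeded coin flip by default (`first` and `abstain` rules are
available). The context-shift statistic is the change in the *absolute*
utility difference between contexts, `| |ΔU|_in − |ΔU|_out |`. Note a
subtlety: this equals the closed form `(1−β)·w_other·|Δother|` only while
the signed difference keeps its sign across contexts. When discounting
pushes a decision maker through indifference (which happens to a (0.5,
0.5) prosocial on the canonical option pair at β = 2/3), the absolute-value
statistic is smaller than the signed change and is no longer monotone in
β. The implementation always evaluates both contexts explicitly; the
closed form is used only as a test oracle on sign-preserving cases.

## SVO slider scoring

The angle is `arctan((mean_other − 50) / (mean_self − 50))` over the six
primary items, with means taken across items (grand-mean centering at the
item-grid centre of 50). The packaged item table is the standard published
six-item allocation grid; the scoring depends only on the formula.
Classification uses the conventional open intervals — prosocial
(22.45°, 57.15°), individualist (−12.04°, 22.45°), competitive below,
altruistic above — and values exactly on a cutoff are reported as
`boundary` rather than silently binned. Angles map to utility weights by
`(w_own, w_other) = (cos θ, sin θ)`, which preserves the angular geometry
(`arctan(w_other/w_own)` recovers the angle exactly); the alternative
`w_own = 1 − w_other` was considered and rejected because it distorts
ratios at extreme angles.

## Fixation detection (I-DT)

Greedy left-to-right maximal windows: a window grows while the summed
dispersion `(max x − min x) + (max y − min y)` stays within 30 px, and is
emitted as a fixation when its duration reaches 50 ms (inclusive).
Duration counts each sample as one nominal frame — `t_last − t_first +
frame` — so at 120 Hz exactly six samples meet the 50 ms minimum; without
the trailing frame six samples would span only 41.7 ms and the printed
minimum would be unreachable at the printed sampling rate. The frame
length is inferred as the median inter-sample interval. The detector is
tested for exact equivalence against a brute-force oracle that rescans
every candidate window from scratch, on thousands of random inputs up to
50 samples.

AOI rectangles are half-open (`[x0, x0+w) × [y0, y0+h)`, origin top-left,
y downward, 0-based pixels): a centroid on the top-left corner belongs to
the AOI, one on the far edge does not. Layouts are validated for
on-screen placement and pairwise non-overlap.

## Trial metrics and exclusions

Per trial: response time, number of fixations, number and proportion of
distinct inspected AOIs (denominator 15 = 8 payoff cells + 4 row labels +
3 identity boxes), attention to own outcomes as `100 · dwell(own) /
(dwell(own) + dwell(other))` over the payoff cells only (derived
difference/sum cells and labels are excluded from this contrast; their
dwell is still reported for sensitivity checks), and dwell shares over the
three identity boxes (group membership, coin toss, personal code).

Exclusions run in a fixed order: participant-level manipulation-check
flags; then trials with under 50% of fixations on payoff + identity AOIs;
then response times under 200 ms or above the pooled mean + 3 SD, where
the mean and SD are computed over the trials surviving the fixation-share
filter (passing frozen statistics makes the filter idempotent); then,
for process analyses only, trials whose group-membership AOI received no
gaze sample at all (attendance is judged on raw samples, not fixations).
The RT statistics are pooled across participants and include filler
trials, matching the "overall mean decision time" reading; both choices
are single switches away if a per-participant or target-only variant is
wanted.

## Drift-diffusion simulator

Evidence (the relative decision value) starts at 0 and accumulates by
Euler–Maruyama steps `drift · dt + σ·√dt · N(0,1)` until absorption at
±a. While option A is fixated, drift = `d · (U_A − θ·U_B)`; fixations
alternate between options with log-normal durations (median 350 ms,
σ_log 0.4), first side uniform. RT = first-passage time + non-decision
time. Defaults: `d = 0.002` (evidence/ms per utility unit), `σ = 0.018`
(evidence/√ms), `a = 1`, `θ = 1`, non-decision 300 ms, `dt = 1` ms,
horizon 20 s (unabsorbed trials are flagged censored, ~0 at defaults).

`θ = 1` — the gaze-independent plain-DDM regime — is the default: with
the design-scale payoff variability, gaze-contingent discounting (fully
supported via `θ < 1`) produces the same qualitative predictions with
more noise, and the plain regime admits the closed-form check
`P(A) = 1/(1 + exp(−2·a·d·ΔU/σ²))`. The discrete absorption check uses a
threshold lowered by `0.5826·σ·√dt` (the standard continuity correction
for discretely monitored barriers), which brings simulated choice
probabilities onto the continuous closed form to within Monte-Carlo
error. The drift/noise scale was set so that the utility differences
produced by the trial generator span the model's sensitive range: mean
RTs land at 1–3 s, and the planted context effects on choice and effort
are expressed clearly at the emulated design's sample sizes rather than drowned in
first-passage noise.

The cohort simulator turns option-level fixations into AOI-level
attention: within the fixated option, the cell is drawn with
probabilities ∝ `(w_own, β·w_other, 0.15, 0.15)` over (own, other,
difference, sum) — attention follows decision weights — and each trial
opens with 3–5 identity-box fixations drawn with a (3, 1, 1) bias toward
the group-membership box (≈ 60/20/20 dwell shares). A small probability
(0.02) of skipping the identity box entirely yields the group-unattended
trials the exclusion stage needs. Response time is the accumulation time
plus identity/label dwell, so per-trial AOI dwell can never exceed RT.

## Synthetic experiments

Each participant receives 40 ingroup and 40 outgroup trials (28 target +
12 filler each) in randomised order, prosocial option side drawn per
trial. Target payoffs come from truncated normal laws on the design
ranges; per trial two own-payoff draws are sorted (larger → selfish
option) and two partner draws anti-sorted (larger → prosocial option), and
pairs violating dictator dominance (`own > other` within both options) are
redrawn, so every trial is a genuine trade-off with differing sums. The
underlying location/scale (own: 8.90/8.0; other: 2.19/8.0) are calibrated
so the emitted marginals match the design means (7.18 and 3.03 €). The
design dispersions (SD 2.04 and 2.22) are not jointly attainable with
these ranges and means under any truncated normal — the partner-payoff
target SD equals the uniform-law SD on that range — so the emitted SDs
land at ≈1.85/1.89, the closest the family allows. Fillers are drawn from
the same law and flagged.

SVO angles come from a two-component normal mixture, 65% prosocial
(mean 32°, SD 8°) and 35% individualist (mean 8°, SD 8°), a typical
slider-measure composition for student samples.

Raw gaze is generated as the inverse of preprocessing: `round(dur/frame)`
samples per planted fixation, jittered around the AOI centroid with
truncated Gaussian noise (σ 3 px default, hard-clipped at ±7 px per axis
so a planted fixation's own dispersion, ≤ 28 px, can never break the
30 px tolerance — detected fixations are bounded-dispersion by
definition, so the clip reflects what the detector can see rather than
raw eye-tracker noise), plus two un-jittered saccade samples at 1/3 and
2/3 of the path between fixations — too far from either cluster to join
a window and too far apart to form one. The round trip
generate → detect → assign therefore recovers planted AOI dwell
sequences essentially always for noise up to 5 px; sub-50 ms plants are
correctly invisible.

What the generator does **not** emulate: blinks and tracking dropouts,
smooth pursuit, calibration drift, saccade curvature and overshoot,
pupil dynamics, any dependence of fixation durations on content, or
serial position effects beyond a linear trial index. Passing round-trip
and recovery tests therefore certifies the pipeline's internal
consistency, not robustness to real-world eye-tracking artefacts.

## Regression models

Choice: repeated-measures logistic regression of the prosocial choice on
SVO angle, group setting (0 = outgroup, 1 = ingroup) and their
interaction, controlling for the percentage of monetary disadvantage of
the prosocial option, `100·(own_s − own_p)/own_s`, and the efficiency
(joint-outcome) difference `(own_p + other_p) − (own_s + other_s)`; both
control definitions are declared assumptions (the canonical option pair
gives 8% and 0.30). Attention and effort (log RT, log fixation count,
proportion inspected): linear models on SVO × group plus a trial-order
control. All predictors are centered; the interaction inference is
invariant to the centering constants. Random-effects structure is a
participant random intercept (random group slope available behind a
flag).

Backends: the binary mixed model is statsmodels' variational-Bayes
binomial mixed GLM; linear mixed models use REML `MixedLM`. For
simulation loops (power, recovery) a population-averaged GEE backend with
exchangeable working correlation is used instead: it is an order of
magnitude faster, estimates the same signs, and with the Mancl–DeRouen
bias-reduced sandwich covariance plus a t reference on
(clusters − parameters) degrees of freedom its type-I error is near
nominal at the cohort sizes involved (measured ≈ 0.05 per effect on
zero-effect frames at 80 clusters). Plain GLM/OLS backends exist for
closed-form checks (a 2×2 logistic fit reproduces the contingency odds
ratio). Non-convergence is flagged on the result, not raised. No
multiple-testing correction is applied; tests are two-sided at 0.05.

## Monte-Carlo power

The sampling frame is a generative random-intercept model on the linear
predictor scale (Bernoulli-logit or Gaussian), with per-participant SVO
draws and `trials_per_context` trials in each group context. For each
sample size n: simulate a cohort, refit, record rejections per effect;
power is the rejection rate over 500 replications (default), repeated
under at least two base seeds so the seed-to-seed spread is visible in
the output. Zero-effect frames reject at the nominal rate; with strong
main effects and a weak interaction, main-effect power saturates at much
smaller n than interaction power — the qualitative sample-size asymmetry
that motivates simulating power for interaction hypotheses rather than
relying on main-effect heuristics.

## Problem sizes used in the shipped checks

The test suite exercises the detector/oracle equivalence on 1000+ random
snippets (≤ 50 samples), the gaze round trip on 500 seeded trials at
σ = 5 px, the closed-form DDM limit at 10,000 trials per utility
difference, directional parameter recovery on 50 cohorts of 80
participants × 56 target trials, and power calibration at 500
replications × 2 seeds. These sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances while keeping the full suite
in the minutes range on a single core.

## Known limitations

- Only the identity payoff transform is implemented; curvature, inequity
  aversion, reciprocity and multi-alternative races are out of scope.
- The aDDM is used generatively; there is no likelihood-based parameter
  fitting to data.
- The variational-Bayes mixed logistic gives slightly optimistic posterior
  SDs relative to full MCMC; use the GEE backend when calibrated
  inference matters.
- Binocular averaging is a preprocessing convention here (single-eye
  streams pass through unchanged); no eye-specific validity modelling.
- The synthetic payoff law reproduces the design ranges and means but not
  the printed dispersions (see above), and filler-trial structure is an
  assumption (same law, flagged).
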