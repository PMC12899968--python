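# Methods

## The task and the generative model

One stop-signal task condition presents 200 trials: 150 go (75%) and 50
stop (25%). Trials begin with a 500 ms fixation cross, then a stimulus
for up to 1000 ms; responses are a two-choice frame-colour discrimination
(key 1 red, key 3 yellow). Stop trials present the gray-background
version of the stimulus after a stop-signal delay (SSD) that a 1-up/1-down
staircase moves in 50 ms steps within [50, 1000] ms, starting at 250 ms:
up after successful inhibition, down after a failure, so the procedure
tracks the 50% inhibition point. ITIs are drawn independently and
uniformly from {1500, 1700, 2000} ms. Session order (food first vs.
neutral first) alternates with participant index, giving an exact 50/50
split in even cohorts.

Configuration bookkeeping: each of the 25 images × 4 variants appears
exactly twice across a condition's 200 trials, reproducing the stated
"100 unique configurations presented twice". Because only 50 trials are
stop trials while 100 configuration slots carry gray backgrounds, the
plan's `variant` column is treated as a configuration *label*: the
displayed go stimulus is always the white version of the image, and on
stop trials the gray version of the trial's configuration appears as the
stop signal. Stop positions are uniformly interleaved by default; an
optional `max_consecutive_stops` cap (off by default) constrains runs
via a placement-repair pass.

Behavior is simulated as an **independent horse race**. The go process
finishing time is ex-Gaussian — Normal(μ, σ) plus an independent
Exponential(τ) tail, the standard positively skewed RT model — with
defaults μ = 440 ms, σ = 50 ms, τ = 90 ms (mean go RT 530 ms, in the
520–540 ms range typical of this population). The stop process finishing
time is Normal(220, 30) ms truncated at zero, independent of the go
process. A response escapes on a stop trial iff the go process finishes
before SSD + T_stop and within the 1000 ms window. Trigger failures
(stop process never launched), go omissions and choice errors are
exposed as probabilities but default to 0; the behavioral QC rules only
bite when such pathologies exist.

Cohort synthesis emulates a 61-person study (30 regular-activity RPG, 31
inactive IAG) with a default true-SSRT disadvantage of 33 ms for IAG
(the observed group difference scale), between-subject SDs of 35 ms
(SSRT) and 55 ms (go μ), demographics drawn per group on the scales of
the published demographics table, IPAQ minutes drawn by bounded
rejection so each participant satisfies their group's classification
rule, and ROI contrast values generated per participant × condition ×
ROI as cell mean + Gaussian noise, with an optional coupling that
induces a chosen correlation with MET-minutes. One RNG stream per
participant is derived from (cohort seed, participant index), so cohorts
are fully reproducible and participants independent. Note the published
inactive-group METs mean (631 ± 713) sits above the 600 MET-min/week
classification threshold; the generator enforces the rule, so its IAG
METs distribution is truncated below 600 — a deliberate divergence in
favour of internal consistency.

## SSRT estimation and QC

The integration method with replacement: p = p(respond|signal) is the
proportion of stop trials with a response; go RTs (all responded go
trials by default — a response is a response in the race; a
`correct-only` pool is available) are sorted ascending after replacing
omissions and over-window RTs with the participant's maximum valid go
RT; the nth RT is the order statistic at rank ⌈p·N⌉ (floored at rank 1);
SSRT = nth RT − mean SSD over all stop trials, separately per condition.
The rank rule is the order-statistic convention; `floor` and `linear`
interpolation variants are exposed as options. Replacement affects only
the SSRT distribution; go accuracy and omission rates use the raw
records.

QC excludes a participant when (strict inequalities, as printed): mean
failed-stop RT exceeds mean go RT (a race-assumption violation),
p(respond|signal) < 25% or > 75%, or go omissions > 20%. QC is evaluated
per condition; by default a failure in either condition excludes the
participant from both (whole-person exclusion), configurable.

## Group statistics

The 2 × 2 repeated-measures ANCOVA is computed as the split-plot
decomposition. Between stratum: OLS of subject means on group
(effect-coded) plus mean-centered covariates; the group F has
(1, N − 2 − p) denominator df — with 61 participants and the 5 default
covariates (age, sex, BMI, depression, composite appetite) that is
(1, 54). Within stratum: orthonormal Helmert contrast scores regressed
on group; the within main effect tests the intercepts, the interaction
the group slopes, each with (k−1)(N−2) error df. Covariates do not enter
the within stratum (no covariate × within-factor interactions), a
standard rm-ANCOVA choice consistent with the between-df arithmetic
above. Greenhouse–Geisser ε is estimated from the pooled contrast-score
residual covariance and applied when below 1; with two within levels
sphericity is trivial and ε = 1 exactly, but the machinery generalizes
to k > 2. Effect sizes are partial η² by default (classical η² also
reported). Post hoc group comparisons per stimulus level are
Bonferroni-adjusted, p_adj = min(1, k·p), k defaulting to the number of
within levels (configurable, since the original post hoc family size is
ambiguous between 2 and 4).

The no-covariate case is verified in the test suite against
`pingouin.mixed_anova` and against a hand-computed paired-contrast F on
a balanced six-participant fixture; the null calibration of the group
and interaction tests is checked by simulation (500 null cohorts;
rejection within the binomial band around 5%).

Demographics: pooled-variance t-tests by default (Welch optional — the
original analysis does not state which), chi-square on the 2×2 sex table
without continuity correction by default (the uncorrected statistic
reproduces the significance of the published 24/6 vs. 17/14 split;
correction is a flag). ROI correlations are Pearson r per ROI ×
condition against SSRT and METs, flagged exploratory with no
multiplicity correction. The sensitivity ladder re-runs the ANCOVA under
the four nested covariate sets — {age, sex, BMI, BDI, appetite}, minus
BMI, minus sex, and the minimal {age, BDI, appetite} — and tabulates F,
p, and partial η² per effect per model.

## First-level GLM (scaled down)

Each trial maps to one of eight event types by condition × trial type ×
correctness (omitted go trials count as incorrect; inhibited stop trials
as correct). Zero-duration event trains are convolved with the canonical
double-gamma HRF (peak 6 s, undershoot 16 s, dispersions 1, ratio 6,
32 s kernel — the community defaults) and its first-order temporal
derivative via nilearn, which oversamples the event train internally so
duration-0 events at TR = 2 s do not alias, then sampled at scan onsets.
Six motion nuisance columns (synthesized as low-amplitude integrated
noise; no initial-volume discard, which is a preprocessing step out of
scope here) and an intercept complete the 23-column design. Empty event
types keep all-zero columns (with a warning) so contrast weights stay
aligned. Contrast values are w'β from OLS, with SE from the residual
variance; `stopcor>baseline` weights the stopcor HRF column alone
(implicit-baseline convention), derivative and nuisance columns always
carry zero weight, and contrasts can be restricted to one condition to
feed the group model. Each condition is modeled as its own run.

The group stage ("flexible factorial") delegates to the rm-ANCOVA on
per-participant, per-stimulus contrast values and decomposes a
significant interaction into simple effects (group per stimulus,
stimulus per group, Bonferroni over the four tests).

Sphere ROIs are enumerated on an axis-aligned grid (3 mm default):
member voxels are grid points whose centers lie within the radius
(inclusive) of the center, which is snapped to the nearest grid point;
the canonical 8 mm inferior-frontal sphere at MNI (51, 16, 18) contains
81 voxels. Whole-brain voxelwise inference, smoothing and cluster-level
FWE correction are out of scope; the original thresholds are recorded as
constants for documentation only.

## What the synthetic data do and do not show

The generator reproduces the *structure* the analysis assumes —
staircase-tracked inhibition near 50%, race-consistent failed-stop RTs,
group covariate differences, ROI interaction patterns — under exactly
known parameters, which is what permits recovery and calibration tests
(SSRT recovery within 15 ms in the mean over 200 participants; type-I
error at nominal level). It does not emulate real-data pathologies
(RT drifts, fatigue, staircase non-stationarity, scanner artefacts,
correlated covariates), so passing tests certify the estimators and
inference machinery, not robustness to such violations. Problem sizes in
the test suite (e.g. 30–200 simulated participants, 500 null
replicates, 1,000 random logs) were chosen as the smallest that make the
corresponding statistical bands tight enough to be meaningful.

## Numerical and degenerate-input choices

Truncated-normal stop times use rejection sampling (acceptance ≈ 1 for
mean ≫ sd). The staircase clamps, never reflects, at its bounds. An
all-inhibited participant (p = 0) takes the minimum-rank go RT — flagged
by QC anyway. Scoring requires ≥1 stop trial and ≥1 valid go RT and
raises otherwise; correlations require n ≥ 3; rank-deficient designs
raise an error naming the collinear columns; a zero-variance-everywhere
demographic comparison raises a degenerate-input error rather than
returning p = NaN.
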