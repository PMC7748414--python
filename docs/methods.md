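# Methods

## Task model and outcome rules

A session is an ordered list of go/no-go trials. Stimulus trials carry a
contrast in (0, 1]; blank trials carry contrast 0. Times are seconds from
stimulus onset. The response interval is the closed `[delay_s,
response_window_s]` (defaults 0.25 s and 4 s): a first lick inside it makes a
Hit (stimulus) or False Alarm (blank); no in-interval lick makes a Miss or
Correct Rejection. Licks inside the pre-stimulus timeout window `[-1.5 s, 0)`
abort the trial; aborted trials are kept in files but excluded from every
metric. Two boundary conventions are deliberate and tested: licks exactly at
the delay or exactly at the window edge count as responses, and pre-stimulus
licks earlier than the timeout window are ignored (the task punishes only the
1.5 s window). Licks between onset and the delay are not responses — in the
task they were unrewarded — so a stimulus trial whose only lick lands in
`[0, delay)` is a Miss.

## The censored-latency aROC

Misses and Correct Rejections enter the latency comparison with the surrogate
timestamp 4.1 s, just past the response window, so that differences in lick
probability (not only timing) move the statistic. Latencies are mapped to
100 ms bins over `[0, 4]` s (a latency exactly at 4.0 s falls in the last
in-window bin); the surrogate occupies its own terminal bin. The ROC curve is
swept over bin edges with "stimulus responds earlier" positive, and its
trapezoid area is accumulated exactly in integer pair counts, which makes it
identically the tie-corrected rank statistic
`P(L_s < L_b) + ½ P(L_s = L_b)` on binned values. This gives exact values at
the analytic limits (identical samples → 0.5, fully separated → 1.0) rather
than floating-point approximations. Whether to integrate the binned or the
raw empirical CDF was an open choice; the binned construction is adopted
because the 100 ms binning is part of the metric's definition, and the
pairwise-oracle equivalence is enforced by property test.

## Windowed signal-detection statistics

Hit and false-alarm rates for a truncated window `w` count first licks at or
before `w`; d′ = Φ⁻¹(hit) − Φ⁻¹(fa) after clipping rates to
`[1/(2N), 1 − 1/(2N)]` per trial type (a standard correction keeping d′
finite at extreme rates; the alternative log-linear correction would change
values only at those extremes). The optimal-window search evaluates d′ over a
grid (default 0.1 … 4.0 s in 0.1 s steps, matching the latency binning) and
breaks ties toward the shortest window.

## Learning curves, slopes, criterion

Per animal-day metrics are aROC, mean Hit latency, and latency variability
(sample variance / mean of Hit latencies, units of seconds; ≥ 2 latencies
required). Population curves are unweighted animal means per day; missing
animal-days drop out of that day's mean. Learning speed is the OLS slope of
aROC on day (population-mean fit, with per-animal fits available); the fit's
p-value is the slope F-test. For a zero-residual degenerate series the
p-value is defined as 1 for a flat line and 0 for a perfectly sloped one.
Learning is complete on the last day of the first run of four consecutive
sessions with aROC strictly above 0.8. Strict ">" follows the procedural
definition of the criterion; the threshold and run length are arguments.

Group slope contrasts use z = (b₁ − b₂)/√(se₁² + se₂²) with a two-sided
normal p. A "Fisher z-test" on slopes admits more than one reading (e.g. via
correlation transforms); the difference-of-slopes z on independent standard
errors is the interpretation implemented, chosen because it uses exactly the
quantities the slope fits provide. Unpaired and paired group comparisons use
Mann-Whitney U and Wilcoxon signed-rank (two-sided); an all-zero-difference
paired comparison is degenerate and returns p = 1 with a warning.

## Psychometrics

The psychometric function is the standard ratio-form Weibull
Ψ(x) = γ + (1 − γ − λ)(1 − e^−(x/α)^β) on percent contrast, threshold α,
slope β. (A subtractive form "x − α" sometimes appears in print; it is not a
valid Weibull parameterization — Ψ(0) would not equal γ — and the ratio form
is what the standard psychophysics toolboxes fit.) γ is fixed at the measured
0%-contrast aROC (0.5 when absent) since γ *is* the blank-anchor performance;
λ is free in [0, 0.1] — an upper bound is needed because seven points cannot
jointly pin a large lapse and the threshold, and 0.1 is a conventional cap;
α ∈ (0, 100], β ∈ (0, 10]. The loss is unweighted least squares on aROC
values (the fitted quantity is itself a summary statistic, not trial
counts, so a binomial likelihood would be fiction), multi-started over
α ∈ {4, 8, 16, 32, 64} and β ∈ {1, 2}. An α pinned at the upper bound flags
an uninformative (flat) data set.

Silencing is summarized by MI = (α_on − α_off)/(α_on + α_off) and the fold
change α_on/α_off. Group-level fold changes are reported as the ratio of
group-mean thresholds (matching how grouped thresholds are conventionally
compared, and less biased than averaging per-animal ratios).

## Collicular activity

PSTHs are trial-averaged spike counts divided by bin width. The evoked
response per contrast is the mean rate in the first 100 ms after onset minus
the mean rate in the 100 ms before onset — the "first 100 ms" phrasing could
denote either epoch, so both windows are arguments — normalized to the
maximum across contrasts of the control (LED off) condition. The
contrast-response function is fitted by bounded least squares
(r_max ∈ (0, 2], n ∈ (0, 6], x50 ∈ (0, 100]) with multi-start, and is
monotone for any returned parameters. The depth profile reports, per depth,
the silenced/control ratio of the highest-contrast evoked response (control
≡ 1); the highest contrast is used because it is the strongest and least
noisy point. Layer labels (SGS/SO/SI) attach to nominal depth ranges
0–300/300–500/500–900 µm; functional depth alignment (CSD) is out of scope.

## The synthetic generator

The generator replaces animal data and defines the conditions every
downstream number is computed under.

**Behavior.** Each training day has a schedule: lick probability, latency
mean and CV for stimulus trials at full contrast, and the same for blanks.
First-lick latencies are Gamma distributed (mean/CV parameterization) and
truncated to the response interval by inverse-CDF — positive, right-skewed,
the empirical shape of lick latencies. Detection probability at contrast c is
`q(c) = q_blank + (q_stim − q_blank)·F_w(c; α′, β)` with Weibull CDF `F_w`,
generating threshold α′ = α_gen off-LED and α_gen × silencing_fold on-LED
(so the silenced psychometric curve is exactly the control curve shifted
rightward in log contrast). Near threshold the stimulus latency mean is
inflated by `1 + 0.5·(1 − F_w(c))` — plausible slowing for barely visible
stimuli; the 0.5 is a named constant. Exactly ⌊fraction·n⌋ LED trials are
interleaved at random positions. Blanks are Bernoulli with probability 0.25
by default (training blocks interleave one trial per contrast including 0%).
Spontaneous licking during the gray-screen period is a Gamma-renewal train
(mean ILI 1.3 s, shape 4 — a refractory, pacemaker-like rhythm rather than
Poisson), placed before the timeout window; a 4% per-trial abort probability
plants a timeout-window lick, so aborted trials exist and are exercised
downstream.

**Schedules.** Anchor days interpolate linearly field by field. Intact: day 1
has identical stimulus and blank schedules (q = 0.90, μ = 1.0 s, CV 0.8), so
day-1 aROC is 0.5 by construction; day 4 uses the published population values
(q_stim 0.899, q_blank 0.816, μ_stim 0.77 s, μ_blank 1.01 s, CV 0.6); day 14
pins q_stim 0.97 and μ_stim 0.52 s. The remaining trained-day constants are
not published and were fixed once by brute-force cohort simulation
(`scripts/calibrate_profiles.py`) against three population anchors — trained
aROC 0.86, learning slope 0.028/day, trained latency variance/mean 0.12 s —
yielding q_blank 0.68, CV_stim 0.55, μ_blank 1.6 s, CV_blank 0.85. CV_stim
comes out above the untruncated value implied by variance/mean = 0.12
(≈ 0.48) precisely because truncation at the 0.25 s delay removes left-tail
mass and shrinks realized variance. The retro-Cre injection control and the
tectal-projection (CT) ablation group share the intact schedule during
learning (CT ablation does not affect acquisition; its effect is a blunted
silencing threshold shift, silencing_fold 1.2 instead of 3.4). The
striatal-projection (CSt) ablation group shares day 1 and reaches, by the
same calibration, a day-14 schedule producing aROC ≈ 0.68 and slope
≈ 0.014/day, then continues linearly to the intact plateau by day 21; the
full cortical lesion group is slightly slower still (day-14 aROC ≈ 0.63).
Silencing folds decay from 3.4 (early training) to 1.5 (prolonged training).

**Spikes.** Poisson counts with rate `baseline + gain·[retinal(depth) +
cortical(depth)·training_scale·(1 − led)]·CRF(contrast)`; retinal weight is
high superficially (0.9) and moderate at depth (0.35), cortical weight is
confined to cortico-recipient depths ≥ 300 µm (0.6 vs 0.05 superficially).
Silencing removes exactly the cortical term; prolonged training shrinks it
via `training_scale`.

**Seeding.** One master integer seed feeds a `numpy.random.SeedSequence`
spawn tree (cohort → mouse → day), so per-mouse streams are independent,
platform-stable, and the whole cohort is reproducible.

**What the generator does not emulate** — and therefore what passing tests do
not certify about real data: within-session motivation/satiety drift, licking
bouts beyond the first response lick, reward-size effects, eye position,
session-to-session autocorrelation within an animal (days are independent
given the schedule), and any within-animal individuality beyond seed noise
(all mice of a group share one schedule). Tests against this generator
validate the *metrics and fits*, and show that the published population
numbers follow from the published behavioral parameters; they do not validate
the biological claims.

## Problem sizes and numerical choices

Replicated quantities use 20 independently seeded cohorts (8 intact or 5
CSt-ablated mice × 14 days × 240 trials), enough for the replicate-mean
standard error of each anchor to sit well inside its comparison band.
Psychometric recovery uses 6 mice × 8 contrast sessions × 500 trials with the
LED on a third of trials; the training-duration sweep uses three stages by
default in tests (five-stage sweeps resolve the MI trend only with more data
than adjacent stages' noise allows). Optimizer non-convergence from every
start raises a fit-failure error rather than returning garbage; degenerate
inputs (empty samples, < 2 latencies, all-tied paired tests, zero-variance
series) raise typed errors or return flagged defined values as documented
above.

## Known limitations

- The aROC is reported without confidence intervals (out of scope).
- The "Fisher z-test" reading and the strict criterion inequality are
  documented choices; both are configurable at call sites.
- The day-4 emergent pooled aROC of the calibrated generator is ~0.62-0.63
  against the published 0.60 ± 0.03 — the day-4 schedule is fully pinned by
  published values, so this residual is a property of the Gamma-latency
  model, not a tunable.
- CSV I/O targets this package's flat schema only; no attempt is made to
  read vendor lickometer formats.
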