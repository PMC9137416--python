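# Methods

`bcfskit` implements, end to end and on synthetic data with known ground
truth, the analysis chain of an oddball breaking-continuous-flash-suppression
(bCFS) experiment: trial-sequence generation, a diffusion-model account of
response times, EZ-diffusion parameter estimation, EEG preprocessing,
two-level spatiotemporal cluster-permutation statistics, and an
expanding-window change-point procedure for single-trial ERP latencies.
This note records the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic data do and do not establish.

## Task and design model

Trials are organised in blocks of 90 with a 5:6 dominant-expression ratio
(75 standards, 15 deviants per block).  Blocks alternate between
neutral-dominant and fearful-dominant, the starting dominance
counterbalanced across subjects by index parity, and each block opens with
at least two standards.  Deviant gaps (standards between consecutive
deviants) are drawn from a Gaussian with mean 4.5 and SD 1.25, rounded and
resampled until they land in [2, 7]; the mean/SD are not constrained
beyond the printed support, so a symmetric choice over that support is
used.  A full gap vector that cannot fit the block is resampled, up to 100
attempts, after which a design-infeasibility error is raised — determinism
under a seed is preferred to silent constraint violation.  Experiment 1
runs 8 blocks with a 6-s face-contrast ramp against a complementary mask
ramp; Experiment 2 runs 14 blocks with a 3-s ramp to a titrated
subject-specific maximum against a fixed 100%-contrast mask.  ITIs are
drawn uniformly on the stated jitter grids (0.5–1.0 s step 0.1; 0.25–0.50 s
step 0.05).

The titration staircase adjusts face contrast towards a 2-s goal RT with
steps of 10, 8, 6, 4% across the first four reversals and 2% thereafter.
Two independent staircases (one per dominant-emotion block type) each run
across two 90-trial blocks; their final values are averaged.  An RT exactly
at the goal counts as "slow" (contrast increases) — a fixed tie rule chosen
because none is stated.

## Behavioural generator

Per-trial RTs come from a two-boundary Wiener diffusion with unbiased start
(z = a/2), diffusion scale s = 0.1, and RT = Ter + first-passage time.
The walk uses Euler–Maruyama steps at dt = 1 ms with the Brownian-bridge
between-step crossing correction; without the correction the discrete walk
under-detects boundary crossings and biases accuracy and decision time by
an O(sqrt(dt)) amount large enough to matter for EZ recovery (measured:
accuracy 0.813 vs the closed-form 0.802 at v = 0.1, a = 0.14).

Condition effects enter through the non-decision time, reflecting the
design's premise that emotion and surprise act on sensory encoding rather
than on the decision process.  Defaults (seconds):

| parameter | default | meaning |
|---|---|---|
| `ter_baseline` | 1.60 | grand-mean non-decision time; puts mean RT near the task's ~1.8-s operating point |
| `ter_emotion` | −0.08 | fearful minus neutral |
| `ter_expectation_neutral` | +0.05 | unexpected minus expected, neutral blocks |
| `ter_expectation_fearful` | −0.08 | unexpected minus expected, fearful blocks |
| `anxiety_slope_neutral/fearful` | +0.002 / −0.004 | per mean-centred STAI point, applied to the expectation shift |
| `v_mean`, `a_mean` | 0.24, 0.11 | give ~93% accuracy and ~0.2-s mean decision time |
| `ter_subject_sd` | 0.08 | between-subject spread (random intercept) |

Only the *directions* of these effects are dictated by the phenomenon being
modelled (fearful faster; surprise slows neutral and speeds fearful
encoding; the fearful surprise advantage grows with trait anxiety); the
magnitudes are free generator parameters.  They were fixed once so that the
implied RT interaction is 0.13 s and the design's power targets (significant
interaction recovery at N = 32 in ≥ 90% of cohorts) hold, and are not
re-tuned per analysis.  `ter_baseline` matters structurally as well as
cosmetically: with mean RTs near 1.2 s the late slope break at 61% of the
trial sits only ~0.13 s before the 0.3-s pre-response guard, which
truncates the post-break segment and biases late change-point detection;
at the task's actual ~1.8-s RTs the geometry is sound.

## EEG generator

Each responded trial's clean waveform is three linear segments: flat until
the early break, a 4.5 µV/s ramp until the late break, then 13 µV/s until
response.  The early break sits at `early_frac` (default 0.25) of the
trial's RT plus per-condition shifts (fearful −10 ms; unexpected fearful
−20 ms; unexpected neutral +20 ms); the late break at `late_frac` (0.61)
of RT plus a fearful −10 ms shift.  These fractions mirror the observed
positions of the early and late neural events (≈26% and ≈61% of the trial
window) so the synthetic data exercise the same regime the procedure is
used in.  No-response trials carry the first ramp only.  Fearful trials
receive a ×1.3 amplitude gain over the parietal-occipital electrodes in a
1.0–2.2-s band; the gain envelope has raised-cosine edges (0.3 s) because a
hard on/off gain creates step discontinuities that a change-point detector
correctly — but uselessly — locks onto.  On top of the clean signal: a
2-µV 10-Hz mask oscillation with a 0.7-µV 20-Hz harmonic, white noise
(`white_sd` = 0.15 µV per sample at 100 Hz), and 1/f noise synthesised by
spectral shaping of white noise (`pink_sd` = 0.15 µV RMS).

The noise defaults are deliberately on the clean side of real single-trial
EEG.  They define the operating regime in which single-trial change-point
recovery is specified (mean absolute early error ≤ 30 ms, late ≤ 50 ms,
after the pipeline's 200-ms smoothing): at these levels the procedure's
accuracy reflects the algorithm, not the noise floor.  Real recordings are
noisier and carry ocular and muscular artifacts, volume conduction,
trial-to-trial waveform variability and non-piecewise-linear dynamics that
this generator does not emulate, so passing tests establish correctness of
the machinery, not single-trial accuracy on real data — there, the
procedure's outputs are meaningful mainly in aggregate (per subject and
condition), as they are used.

Every simulated epoch carries its true break latencies; only tests and the
validation benchmarks read them.

## Behavioural analysis

Filtering removes incorrect, no-response and sub-500-ms trials, then
applies a per-subject 3-SD rule on each subject's overall surviving RTs
(not per condition).  The EEG-side screen uses 4 SD; both constants are
config fields.  Last-standard selection keeps every deviant and its
immediately preceding surviving standard.

Mixed models are REML fits with a subject random intercept
(statsmodels MixedLM).  Treatment coding defaults to *fearful* and
*expected* as reference levels — the printed sign pattern of the RT models
(positive emotion coefficient alongside faster fearful responses, and an
intercept equal to the expected-fearful cell mean) identifies those
reference levels, so the default reproduces that arithmetic; the coding is
configurable and recorded in every fit.  Wald p-values use a normal
approximation with df reported as infinite and the choice recorded in the
fit object; at the trial counts involved the difference from a
Satterthwaite correction is negligible, and the fits themselves are
checked against R's lme4/lmerTest in the test suite.  EMMs are linear
combinations of fixed effects at each condition cell, averaging over other
categorical covariates and holding mean-centred numerics at zero; on
balanced designs they equal raw cell means (tested).  Model comparisons
refit by ML and use the likelihood-ratio chi-square.  VIFs come from
regressing each fixed-effect column on the others.

The paired Bayes factor is the one-sample JZS BF with a Cauchy(0, 0.707)
effect-size prior, computed through the normal/inverse-gamma mixture
integral (relative tolerance 1e−6) and cross-checked against an
independent noncentral-t quadrature.  The correlation Bayes factor is
Jeffreys' correlation test with the uniform stretched-beta prior — the
convention behind the reported correlation BFs — evaluated by quadrature
of the exact marginal likelihood and cross-checked against pingouin.

## EZ diffusion

The closed form maps (mean RT, RT variance, proportion correct) to
(v, a, Ter) with s = 0.1.  Moments are computed across all responded
trials (correct and incorrect) per subject and condition — the all-trials
convention — with a correct-only option.  pc = 0.5 raises an
undefined-drift error; pc ∈ {0, 1} excludes the subject entirely (all four
conditions); below-chance pc yields negative drift and a flag.  The
estimator satisfies the exact inverse property against the forward moment
map (machine precision) and is scale-equivariant in s.

The 2×2 repeated-measures ANOVAs with experiment as a between factor are
computed by the contrast-score reduction, exact for two-level factors:
each within effect's F is the intercept test of an OLS of the per-subject
contrast score on the effects-coded between factor.  Equality with base
R's `aov` + `Error(subject/...)` is asserted in the tests.  Parameter
estimates are z-scored per subject across its four condition cells by
default (`within_subject`); a `within_cell` alternative (z-scoring each
cell across subjects) is provided because the wording "z-scored each
subject's parameter estimates" admits both readings.

## EEG preprocessing

Pipeline order: average reference → 0.1–45 Hz zero-phase 4th-order
Butterworth band-pass plus 50 Hz IIR notch (Q = 30) → polyphase
downsampling to 100 Hz → GESD artifact screening → −0.1..3-s epochs
(half-open sample convention, time of sample k is start + k/sfreq) →
weighted-neighbour interpolation of bad channels → 200-ms centred boxcar
smoothing (edges shrink) → amplitude rejection → response-locking by
re-indexing (no resampling) → −50..0 ms baseline.  Baseline correction is
applied once to stimulus-locked epochs and propagates.  The GESD screen
uses Rosner's sequential ESD at α = 0.05 on log-variance features
(per-trial pooled over electrodes; per-electrode pooled over trials) with
max outliers defaulting to 20% of observations; the recursion is verified
against a brute-force implementation on all small inputs.  ICA-based
artifact classification is out of scope; the variance screen is the
documented simplified stand-in.  The 20-point boxcar nulls the 10-Hz mask
oscillation (and its 20-Hz harmonic) exactly, which is the reason for the
200-ms window.

## Cluster permutation

Pointwise t statistics are thresholded two-tailed at α = 0.05 on the
appropriate t distribution (the cluster-forming threshold is configurable;
the convention is the named default).  Cluster connectivity is montage
adjacency at the same sample ∪ temporal contiguity at the same electrode;
the statistic is cluster mass (sum of t).  First level: two-sample
contrasts or trial-wise covariate regression with 100 label/covariate
permutations; points outside surviving clusters are zeroed by default
(full maps via flag).  Second level: one-sample sign-flip tests on subject
maps with 500 permutations, or covariate regression with covariate
shuffles.  The observed labelling is always a member of the null set, so
p ≥ 1/(n_perm + 1); exhaustive enumeration replaces sampling for small n,
and the engine warns that 100 permutations bound p-resolution at 0.01.
Familywise calibration (≈5% under i.i.d. Gaussian nulls) and equality
with exhaustive enumeration are asserted in the tests.  The FDR
correlation map applies Benjamini–Hochberg over all electrode×time points
and keeps a point only when at least two adjacent electrodes co-survive at
that sample.

## Change points

`detect_slope_change` minimises the total RSS of two independently fitted
regression lines over the split point (min segment 3 samples; ties to the
earliest split; all computed in O(n) via prefix sums, verified against
exhaustive search).  A constant or purely linear input returns the
earliest admissible split with a degenerate flag.

The expanding-window procedure applies the detector to windows
[0.1 s, 0.1 s + j·50 ms] capped at RT − 0.3 s, and takes a modal detected
latency as the early change point; reversing the window anchor yields the
late change point.  A window is admissible when it holds two 3-sample
segments (so the first window ends at 0.15 s; at RT = 1.5 s there are 22
forward windows).  Three refinements beyond the plain mode, each forced by
measured failure modes and regression-tested:

1. **Degenerate windows do not vote.** Windows preceding signal onset are
   exactly flat; their "best split" is the earliest admissible index, and
   with enough of them that index wins the mode (observed 100+ ms errors
   on noiseless input).
2. **A per-window F screen** ((RSS₁ − RSS₂)/2)/(RSS₂/(m − 4)) at α = 0.01
   additionally drops windows whose split is not a significant slope
   change.  Smoothed noise is autocorrelated, so this screen is
   deliberately weak — it removes only clearly uninformative windows.
3. **Votes are pooled over ±1 sample** before the winner is picked (tie
   direction preserved: earliest for forward, latest for reverse).
   Detections of a true break jitter by about one sample across windows;
   the exact-sample mode splits those votes and lets coherent noise bends
   win, putting the ≤30-ms early-recovery regime out of reach at any
   noise level (measured ~38-ms MAE even at 0.1 µV noise).

Change points are extracted per electrode and averaged over the bilateral
parietal-occipital cluster (P7, P9, PO7, P8, P10, PO8) and the
central-parietal cluster (Cz, CPz, Pz — the printed "Cz, CPz, Cz" is
treated as a typo and the set is configurable).  No early ≤ late ordering
is enforced; violations are flagged and excluded from window durations.
Window durations (initial/middle/late) are z-scored across conditions per
participant and correlated with the EZ parameters (nine correlations,
Bonferroni ×9).  The early/late mixed models mirror the behavioural
engine, with electrode cluster and RT-proportion covariates entering as
fixed effects exactly as specified despite their partial collinearity with
the response (VIF is available for audit).

The (split × window) RSS matrices of the batched detector are evaluated in
float32; prefix-sum differences are taken in float64 first, so noiseless
recovery remains sample-exact while throughput roughly doubles.

## Validation benchmarks and problem sizes

`bcfskit.validation` recomputes the headline figures from scratch:
exact design counts; EZ recovery on a 3×3 (v, a) grid at 100 000 trials
per cell (max relative error ≤ 2%); slope-change agreement with exhaustive
search on 1000 random vectors; change-point recovery on 500 trials at the
default SNR; second-level familywise error over 200 null simulations
(12 subjects × 8 electrodes × 100 samples, 500 permutations); GESD
agreement with the brute-force recursion on 300 small inputs; the boxcar
10-Hz null; JZS quadrature accuracy over a (t, n) grid; and the
direction-replication rates.  Replication cohorts use N = 32 subjects with
2 blocks × 90 trials each (one neutral-, one fearful-dominant) and extract
change points from the deviant + last-standard trials over the two
electrode clusters; these sizes keep a full cohort run under ten seconds
while leaving the power of every monitored effect near ceiling.

## Known limitations

- The piecewise-linear single-trial waveform and the low noise floor are
  idealisations; results transfer to real EEG only at the aggregate level.
- Satterthwaite degrees of freedom are approximated as infinite.
- The GESD artifact features (log variance) are one documented choice among
  many; the test names only the statistic, not the feature.
- Below 1/(n_perm+1), permutation p-values saturate rather than refine.
- The staircase simulation models the contrast-to-RT loop through a
  user-supplied responder; it does not model perceptual noise itself.
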