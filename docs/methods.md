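# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Synthetic spike-train generator

Each neuron is assigned to one of three response profiles and recorded in
its own session: it owns a private block of trials (the `neuron_id` column
of the trial table identifies the session).  The trial timeline is fixed:
scene onset at t = 0 of the trial clock, central fixation at 1000 ms, object
(target) onset at 1700 ms; spikes are simulated from 600 ms before scene
onset to 800 ms after target onset.  Firing is an inhomogeneous Poisson
process sampled by thinning:

    rate(t) = max(0, baseline + gain(cluster, value, direction)
                      * ramp((t - target - latency) / 150 ms))

with `ramp` linear from 0 to 1 and holding the plateau afterwards.  The ramp
shape makes onset, peak, and slope extraction well defined; it is not a
claim about STN response shapes.

Defaults (chosen once, as plausible for primate STN, and then used as the
standing study conditions):

| parameter | default | note |
| --- | --- | --- |
| neurons per cluster | 50 / 50 / 50 | desk-scale campaign |
| trials per scene x value x direction | 20 | trial counts per neuron are not fixed by the recording literature; configurable |
| baseline rate | log-normal, median 20 Hz, sigma 0.3 | per neuron |
| gains (good, bad) contra, Hz | C1 +18/+8, C2 +14/-10, C3 +4/+16 | ipsilateral scaled by 0.4 |
| onset latency | N(100/90/120 ms, 10 ms), floor 30 ms | per trial, per cluster mean |
| accept RT | 130 + 0.5 x latency + N(0, 30) ms | the planted RT-latency link |
| reject RT | accept mean + 80 ms, SD 45 ms | slower and wider; absent on "stay" |
| choice policy | good: accept p = .95 (stable) / .90 (flexible); bad: return/stay/other = .70/.20/.10 (stable), .60/.25/.15 (flexible) | scenes 3-4 are the flexible pair |
| smoothing kernel | Gaussian, sigma 20 ms | carried into all SDF stages |

One master seed spawns independent per-neuron streams, so simulation is
bit-reproducible and neuron subsets are stable.

What the generator does **not** emulate: eye traces and saccade detection
(reaction times and choices are emitted directly), scene-evoked transients
(the planted clusters respond only to targets), biophysical spiking
regularity (Poisson only), hemifield geometry beyond a contra/ipsi label,
session-level nonstationarity, and cross-neuron noise correlations (each
neuron is its own session).  Passing recovery tests therefore demonstrate
the correctness and calibration of the estimators under these assumptions,
not their robustness to the full complexity of real recordings.

## Spike processing

Counts use half-open 1-ms bins `[t, t+1)` with t = 0 at the alignment event
(scene, target, or saccade; the saccade alignment drops "stay" trials with
a logged warning).  The SDF is the count sequence convolved with a unit-area
Gaussian (sigma 20 ms) truncated at 4 sigma with zero padding — mass is
conserved away from the window edges and attenuated within 4 sigma of them;
windows are therefore built with an 80-ms margin around any epoch that is
analyzed.  Large stacks are convolved via FFT; the result matches the direct
path to float precision.

z-scoring uses the 500-ms pre-event baseline of the *aligned* event.  The
baseline mean and SD are pooled per neuron across all of its trials'
baseline bins (stable for low-rate units); a per-trial variant is available
behind a flag.  Zero-baseline-SD neurons are flagged and excluded from
z-based stages rather than propagating NaNs silently.

## Window clustering

Features are each neuron's trial-averaged mean z in 100-300 ms after
contralateral good and bad target onsets (a 2-D profile).  K is selected by
running k-means (10 k-means++ restarts, best inertia) many times per
candidate K in 2..6 with fresh initializations and averaging the silhouette
of each run's partition; 5000 repeats reproduces the full procedure and the
repeat count is configurable because the silhouette mean stabilizes within a
few repeats on desk-scale data (SD across repeats < 0.01).  Euclidean
distance on the raw z features; no re-standardization, since both features
are already on the baseline-z scale.  The K = 3 solution is relabeled
canonically: label 2 = centroid with the most negative bad-object feature
(the value-coding, bad-suppressed profile); of the remaining two, label 1 =
larger good-minus-bad margin (facilitative), label 3 = the bad-preferring
remainder; margin ties break by good feature descending.

## Stacked-condition PCA validation

The 2N x 300 matrix stacks each neuron's trial-averaged contralateral good
response rows above its bad rows (0-300 ms, 1-ms columns).  Columns are
centered and scaled; component signs are fixed by making each loading's
largest-magnitude element positive so score features are reproducible.
Each neuron's PC1-3 scores for the good and bad rows form a 6-D vector,
re-clustered at K = 2 and K = 3; agreement with the window clustering is
reported as a cross-tabulation, not asserted — on default synthetic data the
value-coding cluster is largely preserved, and the first three components
capture more than 60% of the variance.

## Mixed-effects models

`stnpop.mixedlm` implements the Gaussian random-intercepts LMM by profiled
REML/ML over log variance ratios (Nelder-Mead for two factors, bounded
scalar minimization for one).  Each GLS solve uses the Woodbury identity on
the stacked random-effect indicator matrix, so the per-evaluation cost
scales with the number of random-effect levels, not the number of
observations — this is what makes the simulate-and-refit bootstrap loops
affordable.  Estimates agree with statsmodels MixedLM (the independent
cross-check in the test suite) and, for the balanced one-way layout, with
the closed-form ANOVA moment estimators.
Fixed-effect P-values use Satterthwaite denominator degrees of freedom via
the delta method: the variance-parameter covariance comes from a
finite-difference Hessian of the REML criterion and the gradient of
Var(c'beta) from central differences; if the Hessian is not positive
definite the residual df is used and flagged.  The whole-model test is a
parametric bootstrap: the LR statistic of the ML fits (full vs
random-effects-only null) is compared with refits on responses simulated
from the fitted null; p = (1 + #{LR* >= LR}) / (n_ok + 1), with refit
failures counted.  With only two monkeys the monkey variance is weakly
identified; boundary fits are flagged (`singular`), not hidden, and a single
grouping factor is used automatically when only one monkey is present.
Desk-scale default is 199 bootstrap iterations (the full procedure uses
10,000); calibration is verified at 199.

Trial response parameters: onset = first 1-ms bin with z strictly greater
than 2 between target onset and the trial's saccade (the response must
precede the action); peak = max z within 150 ms of onset; slope =
(peak - z(onset)) / elapsed time, zero if the peak falls in the onset bin.
Trials never exceeding the threshold are dropped with a logged count.
Thresholded single-trial onsets carry measurement error, which attenuates a
regression of RT on *measured* latency; the slope-recovery guarantees are
therefore stated for the mixed-model estimator against the generator's true
latencies, and the threshold extraction is verified separately on noiseless
ramps and steps.  Post-hoc condition contrasts are paired t-tests across
neurons within each scene over the four value x direction cells, Bonferroni
corrected within the scene (family size 6).

## Sliding-window choice GLM

Per neuron, contralateral trials, all three reject strategies pooled as
action = -1 (configurable to return-only).  At each 50-ms window (stepped
1 ms, centers reported where the full window fits) the per-trial window
mean is regressed on the +/-1 action code; with this coding the action beta
is half the accept-minus-reject mean difference for balanced classes, and
the generic least-squares solution otherwise.  Display smoothing is a 21-ms
centered moving average with nearest-edge padding (length-preserving).
Heatmap sorting: accept-preferring neurons (positive beta at the peak of
|smoothed beta|) first, then by the first time |smoothed beta| exceeds
2 x the SD of the pre-target betas; all-zero series sort last.  The sort is
a documented convention, not a claim about the original figures.

## Trajectories and divergence time

Per cluster, trial-averaged SDFs for accept and reject (contralateral
trials), baseline-corrected by each row's 500-ms pre-target mean, are
stacked over time samples and decomposed with a single centered (unscaled —
the inputs are rates on a common scale) PCA; both conditions are projected
onto the shared first three components.  The divergence time is the first
post-target sample where the Euclidean distance between the trajectories
exceeds the baseline distance mean + 3 SD, with no persistence requirement.
The baseline statistics use the full 500-ms pre-target window: with a 20-ms
kernel a shorter window estimates sigma_d from too few effectively
independent samples and inflates spurious crossings (~10% of null runs at
300 ms vs ~4% at 500 ms in our calibration).  If the baseline distance is
identically zero, any positive distance diverges at its first sample
(degenerate but well defined).

The recovery harness (`make_divergence_matrices`) plants the separation as
a ramp added in the smoothed-rate domain on top of stationary
true-mean-corrected SDF noise.  Two properties of the full spike path make
a spike-domain planted time ill-defined at millisecond resolution: the
acausal Gaussian kernel spreads an onset backwards by up to 80 ms, and
empirical row centering makes post-target noise non-stationary relative to
the baseline threshold window.  The full path is still checked
qualitatively: on generator data the detected divergence precedes the mean
accept reaction time.

## Decoding

One sample per (neuron, trial): the neuron's 1-ms spike counts in
-600..600 ms around target onset (1200 features), labeled by the trial's
choice or RT.  Because each neuron contributes many non-independent
samples, folds are grouped by neuron in both the outer (performance) and
inner (lambda selection) loops; fold assignment balances sample counts by
greedy packing (largest group into the lightest fold, seeded shuffle for
ties).  Standardization is fit on each training set only — including
separately within each inner fold.  The elastic-net mixing parameter is
fixed at alpha = 0.5; lambda is selected on a glmnet-style grid of 50
values log-spaced four decades down from lambda_max (the smallest penalty
zeroing all coefficients), by inner-CV AUC (choice; logistic loss, fit with
saga on a warm-started descending-lambda path, C = 1/(n lambda)) or MSE
(RT; coordinate-descent elastic net).  Pooled out-of-fold predictions give
the reported AUC or R^2 = 1 - SS_res/SS_tot.  Desk-scale defaults (5 outer /
4 inner folds, 6-8 lambdas, capped saga iterations with a looser tolerance
inside the selection loop where only the lambda ranking matters) are used
throughout the tests; 10/10 folds and the 50-point grid remain the
defaults of record for full-scale runs.

Ablation and single-cluster analyses rerun the entire nested procedure on
subsets.  In the per-(neuron, trial) design, removing a cluster removes its
*samples*, so a full model pooled over informative and uninformative
clusters scores below the informative cluster alone (the uninformative
samples are undecodable by construction) — the expected signature, also
visible in the reported analyses this pipeline reproduces.  A
pseudo-population mode (align the k-th trial per class across neurons and
concatenate features) is provided for sensitivity analyses; there, removing
a cluster removes its feature block and a single informative cluster
matches the full model.  The permutation test shuffles choice labels within
neuron (preserving per-neuron class balance) and repeats the entire nested
procedure; p = (1 + #{AUC* >= AUC}) / (n_perm + 1).

The leakage-contrast harness (`make_leakage_features`) gives each neuron a
distinct random temporal rate profile and an idiosyncratic accept
probability while keeping labels independent of activity given the neuron;
profile rates up to 300 Hz are deliberately exaggerated so that the
neuron-identity shortcut is clearly available to a linear model.  Trial-level
folds then score well above chance while neuron-grouped folds stay at
chance — the contrast that motivates grouping.

## Numerical and tie-breaking conventions

- Bins half-open; t = 0 at the aligned event; epoch means over `[a, b)`.
- Onset threshold "exceeds 2" is strict (`z > 2`).
- Bonferroni thresholds are exact internally (0.05/9), rounded only for
  display.
- k-means ties and centroid-margin ties break deterministically (documented
  in the clustering module); all stochastic steps take explicit seeds and
  the pipeline derives per-stage seeds from one master seed.
- Large arrays are float32 with float64 accumulation for moments; identity
  tests (sliding-GLM betas vs generic least squares, silhouette vs O(N^2)
  enumeration) hold to 1e-10 in float64.

## Known limitations

- The generator's sessions are independent; pseudo-population decoding on
  simulated data therefore lacks the trial-alignment caveats of real
  non-simultaneous recordings.
- Satterthwaite df relies on a finite-difference Hessian; near-boundary
  variance fits fall back to residual df (flagged).
- Thresholded onset latencies are attenuated estimators of the true latency
  (measurement error); the package reports them as defined, and the RT-model
  guarantees quantify the estimator, not the extraction.
- Trajectory divergence uses a single-crossing rule by definition; it is
  sensitive to baseline-window length, which is why the 500-ms window is
  the default here.
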