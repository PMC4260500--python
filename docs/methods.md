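# Methods

`wmlbci` implements a passive brain–computer-interface analysis for
working-memory load (WML): two study designs (within-task classification of
realistic learning materials, and cross-task transfer from controlled
working-memory tasks to algebra word problems), together with a synthetic-EEG
generator that produces sessions with exactly the oscillatory structure the
analysis assumes.  Because no recorded EEG ships with the package, the
generator *is* the data source; everything below states what it emulates,
what it deliberately does not, and which knobs matter.

## The latent-load model

Each trial carries a latent load $W \in [0,1]$ determined by task and
difficulty level, decaying over repeated trials of the same level as the
learner acquires schemata:

$$W_{\text{trial}} = \text{floor} + (\text{base} - \text{floor})\,
  e^{-\lambda\, i},$$

with $i$ the trial index within the level, decay rate $\lambda = 0.02$ per
trial and floor $0.05$ by default.  Within a trial, $W(t)$ equals
$W_{\text{trial}}$ only during the *activation* span (stimulus processing up
to the response) and is zero during rest spans.  This within-trial gating is
what gives the activation/rest interval pair its %ERD/ERS contrast; a load
held constant across the whole trial would, by construction, produce
identically zero ratio features and an unlearnable problem.

Default per-level base loads (n-back .20/.40/.78, reading span .25/.38/.78,
subtraction .08/.35/.62, fraction .35/.60/.88) are spaced so that

* the two retained levels of every task straddle a typical subject's
  personal rating cutoff (classes stay balanced),
* the first subtraction level is by far the easiest condition in the whole
  session and the third fraction level the hardest — so the 2-of-3
  difficulty-level calibration reproducibly drops exactly those,
* the cutoff (mean of the six working-memory block ratings) is robustly
  non-integer; an integer cutoff interacts badly with integer ratings and
  the tie rule and can empty a class.

Subjective ratings follow
$r = \mathrm{clip}(\mathrm{round}(1 + 6W + \varepsilon), 1, 7)$ with
$\varepsilon \sim N(0, 0.2)$ — the simplest monotone link onto the 7-point
scale.  Working-memory tasks are rated once per block (trials inherit the
block rating); learning tasks are rated per trial.

## The forward model

Per channel $c$:

$$x_c(t) = g(t)\,\bigl[\,w^{\theta}_c A_\theta (1 + k_t W(t))\,
  \mathrm{osc}_\theta(t) + w^{\alpha}_c A_\alpha (1 - k_a W(t))\,
  \mathrm{osc}_\alpha(t) + \text{pink}_c(t)\bigr] + \text{artifacts}.$$

* **Oscillators** are narrowband amplitude-modulated sinusoids (6 Hz theta,
  10 Hz alpha; frequency jitter 0.05 Hz, AM depth 0.1) rather than filtered
  noise, so band-power expectations have closed form: $k$ modulates
  *amplitude*, hence expected power ratios are squared factors.  With
  $(1 - k_a) = 0.6$ between full load and rest, the expected parietal alpha
  %ERD is $(0.6^2 - 1)\cdot 100 = -64\%$ — the oracle the tests check with
  an independent Welch periodogram.
* **Topography**: theta weights peak at Fz/FC1/FC2, alpha weights at
  P3/Pz/P4/CP1/CP2, over the ten-electrode montage F3, Fz, F4, FC1, FC2,
  CP1, CP2, P3, Pz, P4 (plus VEOG/HEOG).
* **Drift** $g(t) = 1 + d\sin(2\pi t/T + \varphi)$ ($d = 0.15$, $T = 300$ s
  by default) is a sensor-gain non-stationarity and therefore multiplies
  sources *and* background: that is the multiplicative slow change the
  %ERD/ERS ratio cancels.  Were the background additive outside the gain,
  the ratio would mix scaled and unscaled power and the cancellation claim
  would fail.
* **Artifacts**: Poisson blinks (0.08 /s, 180 µV on VEOG, leaking
  frontally-weighted into EEG channels) and 200-ms bursts of 20–60 Hz noise
  centred on every keypress.
* **Overload reversal** (off by default): above a load threshold the theta
  and alpha modulation signs invert, emulating disengagement under extreme
  load.

Signature strength defaults $k_a = 0.8$, $k_t = 1.0$ and background
$2.5\ \mu$V rms were calibrated **once** so that the full cross-task
pipeline's mean accuracy lands inside the pre-registered 70–90 % band
(16-subject cohorts land around 0.77–0.80), and then frozen.  The effect
size is not taken from any measured data — it is the one free choice the
package makes, and every accuracy produced downstream must be read as a
property of this synthetic effect size, not of real EEG.

What the generator does **not** emulate: volume conduction/head geometry,
event-related potentials, eye-movement rehearsal patterns, 1/f-slope
variation across subjects, broadband beta/gamma, non-Poisson blink
clustering.  Passing tests therefore demonstrate the *pipeline's*
correctness and calibration under the assumed signature, not classifier
performance on recordings.

## Preprocessing

* **EOG regression**: per EEG channel, subtract the least-squares projection
  onto the (centered) EOG channels, coefficients estimated on the full
  recording; a pseudoinverse keeps zero-variance regressors harmless.  The
  operation is idempotent and leaves EOG channels untouched.
* **Interval pairs** (cross-task design): per trial one activation interval
  I_a and one rest interval I_r, cut by task-specific rules (n-back: stimulus
  onset → keypress for I_a, keypress → next stimulus for I_r; reading span:
  the 1000-ms letter presentation vs the post-verification gap; word
  problems: the problem statement vs the post-choice fixation).  Every
  interval respects the keypress-exclusion contract: it ends at least 125 ms
  before and starts at least 125 ms after any keypress.  Time-to-sample
  conversion ceils the start and floors the end (half-open ranges), so the
  guard zone is never sampled even after quantization.  Intervals shorter
  than 250 ms discard the whole trial — the Burg fit needs the samples.
* **Epoching** (within-task design): each 45-s study window yields three
  non-overlapping 15-s epochs; windows whose peak-to-peak amplitude exceeds
  150 µV on any EEG channel are dropped whole.  The threshold is a stand-in
  for an unspecified artifact criterion.

## Spectral estimation and features

AR spectra come from an in-package Burg recursion (forward/backward
prediction-error minimization with Levinson update; reflection coefficients
in (−1, 1) guarantee stability on arbitrarily short windows).  The density
is evaluated *exactly* at the ten integer frequencies 4–13 Hz,

$$P(f) = \sigma^2 \,/\, \bigl(f_s\,\lvert 1 - \textstyle\sum_k a_k
  e^{-2\pi i f k / f_s}\rvert^2\bigr),$$

and band power is the *mean* over a band's integer frequencies (theta 4–7:
four points; alpha 8–13: six points), keeping the two bands on one scale.
Epochs are linearly detrended before fitting so additive drift is not
misattributed to low-frequency poles.  Default AR order is 16 (500 Hz);
the desk-scale configuration uses order 12 at 128 Hz.

Cross-task features are
$\%\text{ERD/ERS} = (P_a - P_r)/P_r \times 100$ per electrode × frequency —
10 × 10 = 100 columns, identical across tasks and subjects.  The ratio is
invariant under any gain common to both intervals (the formal
drift-cancellation property; a paired same-seed run with $d = 0.3$ moves raw
activation band power by ≈ 30–40 % but the features by < 3 %).  Within-task
features are raw alpha band power per electrode on 15-s epochs — the older
design that predates the ratio features; theta is refused in that mode
because the materials differed only in alpha.

## Labeling and calibration

Classes are *subjective*: the personal cutoff is the unweighted mean of all
working-memory block ratings; trials rate > cutoff → high, < cutoff → low,
ties → high (configurable).  The same cutoff labels the learning tasks —
never re-estimated.  Difficulty-level calibration drops, per task, the level
whose mean rating deviates most from the cross-task grand mean, subject to a
post-labeling balance constraint (minority class ≥ 40 %); symmetric ties
drop the lower level.  Feature scaling is z-scoring with population-sd
statistics fit on training rows only and applied unchanged to test rows;
zero-sd columns fall back to sd 1 with a warning.

## Classification and significance

RBF-SVMs throughout.  Hyperparameters (C, γ) come from an inner stratified
3-fold grid search on training data only (default grids $C = 2^{-5..15}$,
$\gamma = 2^{-15..3}$ in coarse log-2 steps); equal scores prefer the cell
nearest the grid centre, because the first-in-order rule would pick the
smoothest corner and degenerate into a constant predictor on featureless
data.  The within-task design uses stratified 10-fold CV with scaling and
search refit inside each fold.  The cross-task design trains one model per
subject on the pooled n-back + reading-span trials and evaluates per trial
on each word-problem task.

Significance uses a permutation test — training labels uniformly shuffled, B
refits, $p = (1 + \#\{\text{perm} \ge \text{obs}\})/(B + 1)$ — with the
**full hyperparameter search re-run inside every permutation** by default.
Freezing (C, γ) at the observed optimum makes the test sharply conservative
(empirically ~0.8 % rejections at nominal 5 %), because tuning on the true
labels is an asymmetry the permutations never see; with the re-search the
statistic is exchangeable and the empirical type-I rate sits near nominal,
limited only by the tie mass of the discrete accuracy statistic under the
add-one ≥ convention.  An exhaustive-enumeration mode covers small sets and
is verified against brute force.

## Problem sizes

Full-scale defaults follow the design (48 n-back trials per level, ~24
reading-span letters per level, 10 problems per level, 500 Hz, B = 1000).
The desk-scale configuration used by the test suite and the analysis
scripts — 128 Hz, AR order 12, 24 n-back trials/level, ~16 letters/level,
10 problems/level, 3×3 grid, B = 79 — keeps cohort-level Monte-Carlo
experiments (200-subject null calibration, signature sweeps) to minutes on
one CPU while preserving every structural element of the pipeline.

## Known limitations

* Reported accuracies quantify the calibrated synthetic effect size, not
  real EEG separability; the within-task design saturates near ceiling
  because 15-s epochs integrate far more signal than the sub-second
  cross-task intervals.
* Single-frequency AR estimates on sub-second windows are noisy and their
  ratio is biased upward (Jensen); band-edge features (8, 13 Hz) carry
  little signal for a narrowband 10-Hz source.
* The permutation test remains slightly conservative for small test sets
  (discrete statistic, ≥-counting); per-subject p-values for the two
  learning tasks share permutation refits and are weakly correlated.
* Uniform label shuffling ignores the block structure of the
  working-memory training labels; with strong residual non-stationarity a
  block-aware scheme would be stricter.
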