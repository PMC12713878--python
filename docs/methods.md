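# Methods

This note documents the models and numerical choices behind
`pup-endotype`: how ventilation and ventilatory drive are estimated from a
single airflow channel, how the four OSA endotypic traits are derived, what
the closed-loop simulator does and does not emulate, and where the open
design decisions were settled.

## 1. Breath segmentation and ventilation

Breaths are delimited at inspiration onsets, detected as
negative-to-positive zero crossings of the flow after a 2-s moving-average
smoothing. Each coarse crossing is then refined to the nearest crossing of
a lightly smoothed copy (0.25-s window, search radius 1 s): a wide kernel
alone drags boundaries toward the larger neighbouring breath, which jitters
breath durations by ~0.2 s and — because ventilation = volume/duration —
injects anticorrelated breath-to-breath noise of several percent that
measurably biases the downstream dynamics fit. With refinement the
ventilation measurement error on synthetic data falls below 0.5%.

Tidal volume is the trapezoidal integral of positive flow over the
inspiratory phase only (onset to the first down-crossing); integrating the
whole breath span would capture the start of the next inspiration whenever
onset detection is slightly late. Crossings closing a breath shorter than
`min_breath_s` = 1.5 s are merged; spans longer than `max_breath_s` = 12 s
are split into zero-volume pseudo-breaths of nominal (median) duration so
that apneas remain represented as 0% ventilation — otherwise apneic periods
would silently vanish from the ventilation signal. The leading and trailing
partial segments of the record are kept as breaths when at least
`min_breath_s` long.

Ventilation per breath is `tidal_volume × 60 / duration` (units/min),
normalized to %eupnea by the time-weighted mean over a centered 420-s
window truncated at the record edges, all breaths (events included)
contributing to the baseline. This published normalization is used for
reporting and the endogram; the dynamics fit uses its own baseline (below).

Context: a breath is `in_event` iff it overlaps a scored respiratory event
at all; it is `in_arousal` iff its midpoint lies inside a scored arousal;
its stage is that of the 30-s epoch containing the midpoint (unstaged
breaths are treated as wake with a warning). Intervals are half-open
`[onset, onset + duration)`, times in seconds from recording start.

## 2. Chemoreflex drive model

Chemical drive deviation d(t) = drive − 100 follows a first-order lag with
pure delay driven by the ventilation disturbance
u(t) = 100 − vent(t − δ):

    τ d'(t) + d(t) = G u(t),     drive = 100 + d,  clamped at 0.

Ventilation is piecewise constant per breath, so the ODE is integrated
exactly (exponential update per constant-input interval, delay applied by
shifting the input in continuous time; pre-record input is eupneic). The
drive attributed to a breath is the state at the breath **start** — the
drive commanding that breath. This convention makes the closed-loop
simulator causal for every δ ≥ 0 and makes estimator/simulator agreement
exact. During scored arousals the total drive adds a wakefulness term γ.

Loop gain is read off the fitted transfer function:
|H(f)| = G/√(1 + (2πfτ)²); LG1 = |H| at 1 cycle/min; LGn = |H| at the
natural frequency f_n solving arctan(2πf_nτ) + 2πf_nδ = π (unique because
the left side is strictly increasing; solved by Brent bracketing on
(0, 1/(2δ)] to machine precision; δ = 0 has no −180° crossing and raises).

## 3. Fitting the drive model

The analysis span is contiguous NREM sleep, split into 420-s windows
advanced by 210 s. A window is fitted when it contains ≥ 1 scored
respiratory event and ≥ `min_fit_breaths` = 10 fit-eligible breaths
(severe-OSA windows physically retain only ~15 open breaths per 7 min, so a
larger floor would reject exactly the nights the method targets). The
residual set is the breaths whose **midpoint** lies outside every scored
event; a breath that merely brushes an event boundary — typically the first
recovery breath, which carries most of the dynamic information — stays in
the fit. The publicly reported `in_event` flag keeps the stricter
any-overlap semantics.

Per window, over a grid of τ ∈ {10, 15, …, 180} s and δ ∈ {2, 4, …, 30} s,
the unit-gain filtered disturbance û is computed once on the whole-night
ventilation (night-mean scale) and the linear subproblem

    vent ≈ b + G·û + γ·A,   G ≥ 0, γ ≥ 0, b free   (A = arousal indicator)

is solved exactly (the intercept is concentrated out by centering; the two
constrained coefficients by active-set enumeration, cross-checked against
`scipy.optimize.nnls`). Two refinements matter in practice:

* **Free eupneic intercept.** The local mean ventilation of a severe-OSA
  window sits below true eupnea. With the baseline pinned at 100 the model
  is misspecified — the true intercept in window scale is
  b = 100(1 + G(1 − µ))/µ for window-mean fraction µ of eupnea — and the
  misfit drags τ to the grid floor, roughly doubling LG1. Inverting the
  fitted intercept, µ = 100(1 + G)/(b + 100G) (clipped to [0.4, 2.5])
  estimates the true eupneic level; window ventilation and drive are
  rescaled by µ so traits refer to model-implied eupnea rather than the raw
  local mean. This also removes the systematic V̇passive/arousal-threshold
  inflation that a depressed baseline otherwise causes.
* **One-sided censoring of covert obstruction.** Achieved ventilation can
  only fall below intended ventilation, so breaths whose residual is below
  −0.5 × (RMS of the positive residuals) are treated as flow-limited
  without a scorable event, dropped, and the window refitted (up to 5
  iterations). This is an upper-envelope fit; it recovers loop gain in
  mildly collapsible patients whose obstruction rarely crosses the scoring
  threshold — the drive-underestimation regime the method is known to
  suffer in.

The grid point with minimal SSE wins. A window is flagged non-identifiable
when the SSE surface is flat (max − min < `tol_flat` = 0.01 × min) or the
disturbance variance over fit breaths is below `var_min` = 1 %eupnea²;
loop-gain values from non-identifiable windows are excluded downstream.
Night-level parameters are per-parameter medians over fitted windows; γ is
fitted per window (a night-global γ was considered and left as future
work). Drive clamping at 0 is applied after fitting, keeping the subproblem
linear.

## 4. Endogram and traits

The endogram partitions breaths into equal-count total-drive bins (100
centile bins with ≥ 1000 breaths, else max(10, n/10)), emitting median
drive, median ventilation and count per bin; breaths are ordered
lexicographically by (drive, ventilation) so the construction is invariant
under permutation of the input, ties included; bins with identical drive
medians are merged. Trait read-off interpolates linearly between bin
medians and clamps (with an extrapolation flag) beyond the range.

Endogram scope is NREM breaths **outside scored arousals and outside a
10-s post-arousal margin**: aroused and just-post-arousal breaths breathe
at drive level through an open airway, and binning them below the arousal
threshold inflates V̇active/compensation by tens of %eupnea on synthetic
nights. The traits characterize the sleeping airway.

* V̇passive = endogram ventilation at 100% drive.
* Arousal threshold = median chemical drive of the breath containing each
  arousal onset (its start-attributed drive precedes the onset); if no
  breath contains the onset, the last breath ending within 30 s before it;
  undefined (flagged) below `min_arousals` usable arousals (5 at night
  scope, 3 per window — a 7-min window holds few arousals).
* V̇active = endogram ventilation at the arousal-threshold drive, clamped
  at 0; compensation = V̇active − V̇passive.
* V̇min = median ventilation of the lowest drive decile (configurable).
* LG1/LGn from the window's fitted parameters.

Night values are per-trait medians over window values; compensation is
recomputed as night V̇active − night V̇passive so the trait identity holds
exactly after aggregation (medians do not commute with differences); its CI
still summarizes the per-window compensation values. Confidence intervals
are 2.5/97.5 percentiles of a seeded bootstrap (windows resampled with
replacement, B = 1000) of the median; a single window yields a degenerate,
flagged CI. Classification against cohort tertiles labels a trait low
(< p33), moderate (≤ p66, boundaries inclusive) or high; the shipped
tertiles cover the MrOS, MESA and CMUH cohorts and no cohort is a default.

Surrogate indices (AHI, F_hypopnea, mean obstructive-apnea duration,
NREM-OAI/NREM-AHI, REM-AHI/NREM-AHI) come from the annotations alone;
events are attributed to REM/NREM by larger epoch overlap, and undefined
ratios are flagged rather than invented.

## 5. The simulator

`simulate_night` iterates breath by breath (default period 4 s):

1. chemical drive from the same delayed first-order chemoreflex as the
   estimator, driven by the achieved (noisy) ventilation — breath-to-breath
   variability circulating through the loop is the physiological excitation
   that makes the dynamics identifiable from spontaneous breathing;
2. airway: when open (arousal, post-arousal, wake) V = drive; else
   V = max(0, V̇passive + slope·(D − 100)) for D ≥ 100 and
   V = min(D, V̇passive) below eupnea (the airway always delivers up to its
   passive capacity; the below-eupnea branch is a stated convention, not an
   inference about real pharynges);
3. arousal fires when chemical drive reaches the threshold at a breath
   start, lasts a fixed `arousal_duration_s` = 10 s (re-triggering allowed
   once it lapses), adds γ to drive and opens the airway for its duration
   plus 5 s — reproducing recovery hyperpnea. The arousal drive applies to
   breaths whose midpoint lies within the scored margins, the same rule the
   estimator uses;
4. multiplicative lognormal noise (σ = 0.05) on achieved ventilation; the
   noisy value feeds back and is emitted as half-sine inspiration/expiration
   flow (25 Hz, eupneic ventilation 7.5 units/min); event auto-scoring uses
   the pre-noise airway output so ground-truth boundaries stay crisp
   (runs of V < 70% eupnea for ≥ 10 s; apnea when the minimum drops below
   10%);
5. stages follow a configurable 30-s schedule (default all N2).

Ground truth: V̇passive and the arousal threshold as programmed,
compensation = slope·(threshold − 100), V̇active by identity, LG1/LGn in
closed form from (G, τ, δ). A configuration whose drive diverges without
bound (slope ≤ −1/G with no finite arousal threshold) is rejected.

What the simulator does **not** emulate: flow-shape changes under
obstruction (flow limitation is purely amplitude reduction), oral
breathing, REM physiology, position effects, SpO2, scorer variability
(events are scored by a fixed rule), or drift in sensor gain. Passing
recovery tests therefore demonstrates correctness of the estimation chain
under the model's own assumptions, not field accuracy on real PSGs.

## 6. Validation experiments and problem sizes

The recovery experiment simulates 20 two-hour nights with independently
drawn traits — V̇passive ~ U[40, 90] %eupnea, threshold ~ U[120, 180],
compensation slope ~ U[−0.1, 0.4], LG1 ~ U[0.4, 0.8] (via τ ~ U[30, 90] s,
δ ~ U[5, 15] s), γ ~ U[10, 30] — runs the full pipeline on each, and
compares night estimates with programmed truth by Spearman correlation and
median absolute error. Two hours per night keeps the whole batch near
20 s while providing ~33 analysis windows per night. Nights whose airway
is too open to score any event (roughly V̇passive ≳ 75 with a modest loop)
are reported as unanalyzable — the correct clinical answer — and excluded
from the recovery statistics.

Oracle checks: the breath-domain filter is compared against an independent
RK4 integration on a grid containing every input discontinuity (100 random
traces); sinusoid probes on a 0.1-s breath grid verify the closed-form
amplitude and phase at five frequencies; a self-consistency fit on data
generated by the model's own equations recovers G and γ to ≈ 1e-15.

## 7. Known limitations

* The arousal threshold estimate carries a positive bias of up to ~10
  %eupnea on nights with frequent immediate re-arousals: the drive at a
  *scored* arousal onset can exceed the underlying trigger threshold when
  the preceding arousal masked the first crossing. This mirrors
  repetitive-arousal scoring on real PSGs.
* In mild airways with covert flow limitation, γ and G·û are nearly
  collinear; the censoring heuristic resolves most but not all such nights,
  and the residual degeneracy (arousal threshold + γ ≈ constant) cannot be
  resolved from scored events alone — flow-shape obstruction measures would
  be required.
* Trait scales refer to model-implied eupnea (via the fitted intercept),
  which corrects severe-night baseline depression but can differ by a few
  percent from the raw local-mean convention of the published tables.
* EDF reading is best-effort via `mne` (channel by label, low-pass sanity
  warning below 12.5 Hz when enabled); CSV is the canonical, fully tested
  format.
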