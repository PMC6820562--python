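# Methods

This note documents the models, conventions and design choices behind
`delaycode`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task and data model

A delayed match-to-sample trial runs on a trial-relative clock: sample
cue onset at t = 0, a 2-s sample phase, delay onset at t = 2 s, delay
offset at `2 + delay_duration`, then a 2-s choice phase. The preceding
inter-trial interval (ITI, uniform 0–10 s) belongs to the trial record
as `iti_before`, and spike times may be negative (pre-cue activity, used
by the pre-stimulus decoding control). Delay durations are exactly 4 s
in the fixed condition and continuous Uniform(1, 7) s in the random
condition. `correct` is defined as `sample == choice` and validated on
load.

All analysis windows are half-open `[start, end)` intervals relative to
one of three alignment events (`cue_on`, `delay_on`, `delay_off`). The
half-open convention makes tiling exact: spike counts over windows that
partition an interval sum to the count over the interval, which is a
property test.

Unless a mode says otherwise, delay-period analyses use correct trials
only and, for the random condition, only trials with delay ≥ 4 s cut at
4 s after delay onset, so both conditions contribute a matched 4-s
window.

## Synthetic sessions

The generator emulates the task's data structure, not its biophysics.
Each unit is an inhomogeneous Poisson process whose rate function
carries one of three delay codes:

* **sequential** — `r(t) = b·g_cond·g_sel·(1 + a·exp(−(t−t_on−c)²/2w²))`,
  a Gaussian bump at `c` seconds after delay onset with width `w` (std);
* **persistent** — `b·g_cond·g_sel·(1 + a)` throughout the delay,
  `b·g_cond` elsewhere;
* **untuned** — constant `b`, no task modulation.

`g_sel` (sample-selectivity gain) applies on preferred-sample trials and
`g_cond` (condition gain) on random-delay trials; both are
multiplicative so that scale-invariant statistics (normalized SDFs, the
sequentiality index) are genuinely exercised. Spikes are drawn by
thinning a homogeneous Poisson process at a known rate bound; the
thinning sampler is validated against Poisson count statistics and a
fine-binned PSTH oracle.

Default parameter ranges (per-unit draws): baselines 0.5–2 Hz for
pyramidal units (matching the low mean rates typical of cortical
pyramidal cells), bump gains 2–6, persistent gains 0.5–1.5, tuning
widths 0.2–0.6 s, selectivity gains 1–1.6, condition gains 0.8–1.3.
These keep a pyramidal unit's session-wide mean rate well below the
8.92-Hz classification threshold even at the top of the gain ranges, so
class labels are recoverable exactly. Interneurons are drawn fast and
narrow (9.5–18 Hz, widths clipped ≤ 248 μs), clear of the 254-μs
boundary on the other side. Trial counts default to ~83 per condition
per day and choice accuracy to 85%, the trained-animal regime.

Two deliberate departures from a textbook Poisson process:

* **A 2-ms absolute refractory period** is imposed on generated trains
  (`enforce_refractory`). A pure Poisson train at a few Hz across ~100
  trials almost surely contains some inter-spike interval < 2 ms, which
  would make every simulated unit fail the cluster-quality screen the
  analysis itself applies. Real neurons have refractory periods; the
  dead-time bias on rates is `r × 2 ms` (< 1% below ~5 Hz) and the
  convergence tests account for it by tolerance. The raw sampler
  `sample_spikes` remains exactly Poisson so its statistical oracles
  stay exact.
* **Named random substreams.** Every stochastic element (trial table,
  each unit × trial spike train, each decoding repeat) draws from a
  generator keyed by the master seed and a stable string key, so adding
  units never perturbs existing ones and any single repeat is
  reproducible in isolation. Derived seeds are kept below 2³¹.

What the generator does **not** emulate: spike-sorting noise, waveform
drift, bursting/adaptation, inter-neuron correlations (units are
conditionally independent given their rate functions), and
within-session nonstationarity. Passing tests therefore show the
analysis chain is correct and calibrated on its stated model, not that
real mPFC data satisfy that model.

## Unit selection

Classification: pyramidal iff rate < 8.92 Hz **and** width ≥ 254 μs
(strict on the rate, inclusive on the width). Quality: min ISI ≥ 2 ms;
L-ratio < 0.10 when the sorter supplies one, absent otherwise and then
not required. The `mean_rate` used for classification is the
session-wide rate from `units.csv`, not a delay-period rate. Inclusion
for delay analyses additionally requires mean rate ≥ 0.5 Hz (inclusive)
in both the fixed-delay and initial-4-s random-delay windows. An
`InclusionReport` is always emitted so the unit accounting is auditable.

## Spike density and half-duration

SDFs use a Gaussian kernel, σ = 100 ms, evaluated on a 10-ms grid;
spikes up to 4σ outside the window contribute, which conserves kernel
mass at the edges (tested to 10⁻³). Normalization is min–max to [0, 1];
a constant SDF cannot be normalized and the unit is excluded from
half-duration statistics with reason "flat SDF".

Half-duration: the peak is the first grid point attaining the maximum;
each side is scanned outward for the first crossing below 0.5 with
linear interpolation between grid points. Both sides cross → the longer
is reported ("two half-durations → the longer one" is read as the two
sides of the single global peak, since a normalized SDF has one maximum
value). One side crosses → that side. Neither crosses (possible only
for idealized plateau inputs) → the longer window-edge distance,
flagged `censored`. Censored values are included in means but carry the
flag so sensitivity analyses can drop them. Condition-averaged SDFs use
correct trials, random-delay trials cut at 4 s. For a Gaussian bump of
width `w` smoothed with kernel σ, the one-sided half-duration is
`sqrt(2 ln 2)·sqrt(w² + σ²) ≈ 1.1774·sqrt(w² + σ²)`, the convolution
identity used as a Monte-Carlo recovery oracle.

## Selectivity statistics

The per-neuron two-factor analysis is a fixed-effects ANOVA on
independent trial observations (the "repeats" are trials; there is no
within-subject pairing at trial level), fit by ordinary least squares
with **Type II** sums of squares so unbalanced cell counts privilege
neither main effect. A unit needs ≥ 2 trials in each of the four
condition × sample cells to be testable. Degenerate conventions: all
responses identical → F = 0, p = 1 for every effect; zero residual
variance with a non-zero effect → F = ∞, p = 0. No multiple-comparison
correction is applied across neurons or bins — population summaries
report raw p < 0.05 proportions, so null data produce a ~5%
false-positive floor by construction (verified as a calibration test).

χ² on responsive proportions is Pearson's on the 2×2 counts table,
df = 1, without continuity correction. Working-memory duration uses
equal-variance two-tailed Student t-tests per 0.5-s bin (Welch is a
config option); a bin with zero variance in both groups scores p = 1
when the means agree and p = 0 otherwise.

## Sequentiality index

The index is the sum of a normalized peak-time entropy and a mean log
ridge-to-background ratio, computed per trial from single-trial SDFs
over the 4-s delay window. Conventions chosen here (exposed as
parameters): ridge half-width 0.25 s, 8 entropy bins over the window,
rates floored at 10⁻³ Hz inside the logarithm, neurons with no spikes
in the window dropped (and counted), peak of a flat-but-nonzero SDF
resolved to the earliest grid point, and at least two contributing
neurons required. Entropy is maximal (1) when peak times tile the bins
uniformly and 0 when all peaks share a bin; the ridge term is 0 for
constant rates. Both terms are ratio- or position-based, so the index
is invariant to multiplying all rates by a positive constant. Absolute
SI values are therefore convention-dependent; only comparisons computed
under one convention (sequential vs persistent, fixed vs random) are
meaningful.

## Decoding

Diagonal LDA: per-class means and a per-unit variance pooled across
classes (shared diagonal covariance), equal priors, ties broken toward
class L; training-fold variances are floored at 10⁻⁶ Hz². Eligibility
criteria are evaluated per unit on the trials of **its own session**
(datasets may pool many sessions): (1) ≥ 15 correct trials per class
after the mode's delay filtering; (2) mean rate ≥ 0.5 Hz over the full
4-s delay window under the mode's alignment; (3) for sliding-window
modes, fewer than 15 zero-spike trials per class in every window.
Offset-aligned random-delay analyses use the last 4 s of delays ≥ 4 s,
windows indexed [−4, 0) from delay offset; on fixed-delay data
offset- and onset-aligned windows are the same time intervals, and
with identical seeds the two paths produce identical accuracies (an
invariant test). SEM is across decoding repetitions, matching how
ensemble decoding error bars are conventionally reported. A
1000-repeat variant for the fixed-vs-random comparison is available
through the repeat-count parameter.

Two statistical properties of this estimator matter when interpreting
null (chance-level) runs, and the test suite measures both:

* **Finite-sample bias.** With 15 + 15 pseudo-trials, each LOOCV fold
  trains on 14 same-class vs 15 other-class trials. The plug-in
  discriminant inherits the estimation-variance asymmetry, giving a
  *conservative* (below-50%) null mean that grows with ensemble size —
  about −3 percentage points at 130 units. This is a property of the
  procedure itself (any plug-in LDA LOOCV at this trial count shares
  it), not an information leak.
* **Pool-level variance.** All repetitions on one dataset reuse each
  unit's finite pool of candidate trials, so a single run's mean
  accuracy inherits the pooled chance structure of those draws
  (empirical SD ≈ 8 percentage points across simulated populations at
  130 units). Chance-level calibration is therefore assessed across
  independent populations: the acceptance script spreads its 100
  repetitions over 50 independently simulated populations, and the
  corresponding test computes its SEM across population means, the
  independent unit of variation.

## Pipeline

`run_all` executes simulate → load → classify → SDF metrics →
selectivity → working-memory bins → sequentiality → decoding, each
stage reading and writing files under the run directory, and records a
manifest with the config hash and per-stage output checksums. Output
files contain no timestamps, so identical config + seed reproduces
identical checksums end to end (tested byte-for-byte on
`summary.json`). A stage failure is recorded and downstream stages are
skipped; the summary still includes every completed section.

## Problem sizes

Simulation-backed tests run at sizes chosen to give their assertions
comfortable statistical margins while keeping the suite quick: e.g.
Poisson mean checks at 200 realizations, the PSTH oracle at 3000
trials × 50-ms bins, type-I-error calibration at 400–500 null units,
label-permutation nulls at 60 permutations, the ensemble-size curve at
15–20 repeats over sizes 10–90, and chance-level decoding calibration
at 10 populations × 10 repeats (the acceptance script uses 50 × 2).
Tolerances are stated in standard-error units wherever the quantity is
stochastic.

## Known limitations

* The analysis assumes the three-CSV layout and trial-relative clock;
  there are no readers for acquisition-system formats.
* L-ratio is accepted as a precomputed column, never computed from
  cluster features.
* The ANOVA treats trials as independent observations; if real data
  carried strong slow drifts, the raw p < 0.05 proportions would be
  anti-conservative. No correction is applied, by design.
* Absolute sequentiality-index values depend on the ridge/bin
  conventions above and are not comparable across conventions.
* The decoder's null mean is conservatively biased at large ensemble
  sizes (see above); comparisons between conditions at matched ensemble
  size are unaffected.
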