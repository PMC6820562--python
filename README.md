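# delaycode

Spike-train analysis of medial prefrontal cortex (mPFC) delay-period
activity in a head-fixed delayed match-to-sample task, where working
memory must bridge either a **fixed** 4-s delay or a **random** delay
drawn uniformly from 1–7 s. The package is for systems neuroscientists
who want a tested, reproducible implementation of the full analysis
chain — unit classification, spike-density metrics, per-neuron
selectivity statistics, a sequentiality index, and pseudo-population
decoding — together with a ground-truth synthetic session generator so
every stage can be validated by parameter recovery without access to
recordings.

## The analyses

**Unit classification.** Units with mean discharge rate < 8.92 Hz and
spike width ≥ 254 μs are putative pyramidal cells; the rest are putative
interneurons. Cluster quality requires no inter-spike interval < 2 ms
and, when available, L-ratio < 0.10. Delay-period analyses include a
pyramidal unit only if its mean rate is ≥ 0.5 Hz during both the entire
fixed delay and the initial 4 s of the random delay (correct trials,
delays ≥ 4 s).

**Spike density and activity half-duration.** A spike density function
(SDF) is the trial-averaged sum of Gaussian kernels (σ = 100 ms) placed
on each spike. After min–max normalization to [0, 1], the *activity
half-duration* is the time from the peak (1) to the half-maximum
crossing (0.5), reporting the longer of the two sides — a width measure
that is small for phasic, sequential firing and censored at the window
edge for persistent firing.

**Selectivity.** Per neuron, a two-factor ANOVA (Type II sums of
squares) on per-trial delay firing rates with factors delay condition
(fixed/random) and sample identity (left/right) plus interaction.
Population proportions of responsive units (p < 0.05) are compared with
a Pearson χ² test on the 2×2 counts table (no continuity correction).
Working-memory duration per unit = number of 0.5-s delay bins (of 8)
with significantly different left-vs-right rates (Student *t*).

**Sequentiality index (SI).** Per trial, `SI = H + R` where `H` is the
Shannon entropy of the neurons' peak-time distribution over 8 bins
spanning the delay (normalized to [0, 1]) and `R` is the mean over
neurons of `log(rate within ±0.25 s of its peak / rate outside)`. High
for sequences, low for persistent codes; invariant to rate scaling.

**Pseudo-population decoding.** For each neuron, 15 left-sample and
15 right-sample correct trials are drawn; pseudo-trial *j* stacks each
neuron's *j*-th draw. Sample identity is decoded by linear discriminant
analysis with a shared **diagonal** covariance (neurons treated as
independent, equal priors) under leave-one-out cross-validation, and
the whole procedure is repeated (default 100×) with fresh neuron and
trial draws; accuracy is mean ± SEM across repeats. Modes cover 2-s
sliding windows (0.1-s steps, onset- or offset-aligned), non-overlapping
2-s windows, an ensemble-size curve on the full 4-s delay, and a 1-s
pre-stimulus control window (correct trials with ITI > 2 s).

## Worked example

Simulate a 120-trial-per-condition day with 30 sequential, 8 persistent
and 8 untuned pyramidal units plus 6 interneurons, and run every stage:

```bash
delaycode run --config config.yaml --out out/
```

with `config.yaml`:

```yaml
seed: 7
simulate:
  n_sequential: 30
  n_persistent: 8
  n_untuned: 8
  n_interneurons: 6
  n_trials_per_condition: 120
decoding:
  n_repeats: 20
  ensemble_size: 20
```

`out/summary.json` from this exact run contains (abridged):

```
inclusion:      52 units, 46 pyramidal, 46 included
half_duration:  fixed 539.3 ± 39.6 ms   random 590.4 ± 41.4 ms   (n = 46)
selectivity:    13/46 condition-responsive, 19/46 sample-responsive
                chi2 = 1.725, p = 0.189
sequentiality:  mean SI fixed 2.374 (99 trials), random 2.392 (52 trials)
decoding:       fixed 86.5 ± 1.7 %, random 83.5 ± 1.6 %  (20-unit ensembles)
```

Reading these numbers: all 46 pyramidal units cleared the 0.5-Hz
inclusion filter; mean half-durations near 0.5–0.6 s say most simulated
units fire phasically (the sequential majority); and 20-unit ensembles
decode the remembered sample far above the 50% chance level because
half the tuned units were given sample selectivity. Each stage is also
a CLI subcommand (`simulate`, `classify`, `sdf`, `selectivity`,
`wmduration`, `si`, `decode`) operating on the same three-CSV data
layout (`trials.csv`, `spikes.csv`, `units.csv`; see
`delaycode.io_core`).

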