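# tremorkit

Quantification of high-frequency tremor from triaxial accelerometer
recordings, built for studies of **primary orthostatic tremor (POT)** — a
rare movement disorder with a 13–18 Hz leg tremor classically elicited on
standing — and in particular for protocols that probe whether the tremor is
driven by *weight-bearing isometric muscle load* rather than upright posture:
a sensor strapped to the proximal fibula records 10 s at 200 Hz in supine,
seated and standing positions and during seated leg-press holds at loads
increasing in 10 kg steps (10 → 100 kg).

## What it computes

For one recording with axes x(t), y(t), z(t) (m/s²):

1. **Vector magnitude** m(t) = √(x² + y² + z²), removing the dependence on
   sensor orientation.
2. **Zero-phase band-pass**: fourth-order Butterworth, 10–22 Hz, applied
   forward–backward — isolates the tremor band from the 1/f accelerometer
   noise floor below and sensor noise above.
3. **Power spectrum** of the filtered magnitude via FFT (one-sided,
   Parseval-consistent; 0.1 Hz resolution at 10 s).
4. **Tremor peak**: frequency f̂ and height of the strongest bin in 10–22 Hz.
5. **Tremor dominance**: the fraction of total signal power within a 0.6 Hz
   window centred on f̂,

   D = Σ<sub>|f−f̂|≤0.3 Hz</sub> P(f) / Σ<sub>f>0</sub> P(f) ∈ [0, 1],

   near 1 for a clear tremor line, near 0 for noise; `D ≥ 0.5` is the
   default presence call.

For a leg-press session it derives the **load threshold** (smallest load at
and beyond which the tremor is *consistently* present), **frequency
stability** (supra-threshold peaks within 0.5 Hz of the standing tremor
frequency) and the **amplitude trend** (Spearman ρ of peak height vs load).
It also ships descriptive cohort summaries, an exact small-sample Spearman
permutation test, and a seeded synthetic-recording generator (gravity +
1/f + white noise + threshold-gated tremor sinusoid) that provides ground
truth for every pipeline property.

## Worked example

```sh
$ tremor simulate --subjects 2 --seed 5 --out demo
wrote 30 recordings for 2 subjects to demo

$ tremor analyze demo/s1/standing.csv
peak 14.90 Hz  height 26.86  dominance 0.927  tremor_present True

$ tremor loadseries demo/s1 --standing demo/s1/standing.csv --out series.json
subject s1: threshold 60 kg
  frequency stable vs standing: True
  amplitude trend rho: 1.000

$ tremor cohort src/tremorkit/data/reference_cohort.tsv
age_years: n=7 mean=70.3 sd=10.2
weight_kg: n=7 mean=75.1 sd=13.3
duration_years: n=7 mean=8.3 sd=4.8
tremor_frequency_hz: n=7 mean=14.94 sd=0.67
```

The standing recording shows a 14.90 Hz peak whose 0.6 Hz neighbourhood
carries 93% of the filtered signal's power — an unambiguous tremor.  The
leg-press session crosses its detection threshold at 60 kg; above it the
peak stays within 0.5 Hz of the standing frequency while its height grows
monotonically with load (ρ = 1.0).  The cohort command reproduces the
summary rows of the bundled seven-patient reference table.

The same operations are importable (`tremorkit.analyze_recording`,
`tremorkit.analyze_load_series`, `tremorkit.simulate_cohort`, ...); the CLI
is a thin wrapper.  JSON reports always embed the `AnalysisConfig` that
produced them.

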