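# glowtrack

Simultaneous molecular-clock, locomotor-activity and sleep rhythm
quantification from time-lapse bioluminescence frame stacks of single flies.

## The problem

A fly carrying a clock-protein::luciferase reporter glows in proportion to
clock gene expression in its peripheral tissues.  Confined to a glass
capillary tube, fed luciferin and imaged in darkness with an ultra-sensitive
camera at one 300-s integration per frame, a single fly yields three
contemporaneous signals per frame:

- **molecular clock** — total background-adjusted photon count in the tube;
- **locomotor activity** — the spatial distribution of those photons along
  the tube: a moving fly smears its light into a rectangle, a resting fly
  concentrates it into a bright spot;
- **sleep** — immobility exceeding five minutes, read as a resting spot that
  stays at the same position across two or more frames.

Because all three rhythms are measured in the *same* animal, paired
single-fly statistics (correlations of rhythm robustness and period between
signals) become possible — something population-level assays cannot do.
`glowtrack` implements the full computational pipeline for such recordings,
plus a synthetic frame-stack simulator with exported ground truth so that
every stage is testable without any camera data.

## The statistics at the core

Each per-fly series (30-min bins) is detrended by dividing by its zero-phase
second-order Butterworth low-pass trend (cutoff 1/72 h⁻¹), removing the slow
exponential luciferin decay and the units with it; the detrended series has
mean 1.  Rhythmicity is the classic autocorrelation statistic

&nbsp;&nbsp;&nbsp;&nbsp;RS = ACF(τ̂) / (2/√n),

the height of the circadian correlogram peak (lag window 14–38 h) over the
95% confidence line `2/√n`; RS > 1.5 defines a rhythmic signal, and the peak
lag, refined by parabolic interpolation, estimates the period τ̂.

## Worked example

Simulate a 12-fly, 2-day recording, run the pipeline, and summarise one fly:

```python
from glowtrack import SimConfig, render_stack, run_pipeline
from glowtrack.pipeline import simulated_layout

cfg = SimConfig(n_days=2.0, image_size=(256, 480), n_columns=12, n_rows=1,
                col_pitch_px=32, seed=7)
rendered = render_stack(cfg)                      # uint16 frames + ground truth
quants, records, geometry = run_pipeline(
    rendered.stack, rendered.markers_in_frame, simulated_layout(cfg))

rec = records[0]
print(f"{geometry.n_tubes} tubes detected; fly 0 summary:")
for kind, res in rec.rhythms.items():
    print(f"  {kind:20s} RS = {res.rs:5.2f}  period = {res.period_h:5.2f} h  "
          f"rhythmic = {res.rhythmic}")
sleep_frac, rest_frac, active_frac = rec.partition_fractions
print(f"  time partition: {100*sleep_frac:.0f}% sleep, "
      f"{100*rest_frac:.0f}% rest, {100*active_frac:.0f}% active")
```

prints

```
12 tubes detected; fly 0 summary:
  clock                RS =  2.32  period = 23.42 h  rhythmic = True
  locomotor            RS =  0.67  period = 23.50 h  rhythmic = False
  sleep_consolidation  RS =  0.31  period = 22.10 h  rhythmic = False
  time partition: 76% sleep, 13% rest, 11% active
```

The clock (true period 24 h here) is recovered as rhythmic with a period of
23.4 h even from this short recording.  Two days (n = 96 bins) is the minimum
the statistic accepts and caps RS near 2.4; behavioural signals, which carry
far more bout-to-bout noise, need the full 7 days to classify reliably — on
7-day runs control flies score clock RS ≈ 8 and behavioural RS ≈ 3–5.

The same stages are available from the shell, one subcommand each:

```
glowtrack simulate --config sim.yaml --out stack.tif --truth truth.json --seed 1
glowtrack detect   --stack stack.tif --layout layout.yaml --out geometry.json
glowtrack quantify --stack stack.tif --layout layout.yaml --out partitions.csv
glowtrack sleep    --partitions partitions.csv --out binned.csv
glowtrack rhythm   --binned binned.csv --out rhythms.csv
glowtrack stats    --rhythms rhythms.csv --out stats.json
```

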