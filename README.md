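# photodyn

Analysis toolkit for event-aligned fiber-photometry-style recordings under
burst-train auditory stimulation, together with a fully parameterised
synthetic-data generator so every stage can be validated without any real
recording.

The pipeline covers:

* **synthetic_data** — stimulus schedules (10 × 500 ms on/off bursts per
  10-s trial at 45/65/85/105 dB SPL, inter-trial gaps drawn from
  {25, 30, 35} s, flat/ramped/damped intensity envelopes) and surrogate
  recordings built from alpha-like response kernels: intensity-scaled dips,
  post-burst rebounds, first-burst onset transients with habituation,
  subject-level random slopes, drift and sensor noise. Pupil-dilation
  series at 30 Hz are also simulated.
* **preprocess** — anti-aliased downsampling (e.g. 2 kHz → 120 Hz),
  per-trial baseline z-scoring (mean/sd of the 5 s before each trial
  onset), 200-ms moving-median smoothing, per-intensity trial averaging
  and burst-window segmentation.
* **metrics** — per-burst onset-referenced peak amplitudes and latencies,
  N2/N1- and P2/P1-style peak ratios, per-subject first/average response
  extrema, and increase/decrease phenotype classification (trial-averaged
  maximum z > 2.58 at any intensity).
* **inference** — pooled OLS of response extrema on intensity with
  subject-level cluster-robust (CR1) standard errors, studentized wild
  cluster bootstrap-t p-values (two-point Mammen weights, null imposed,
  plus-one correction, two-sided), confidence intervals by test inversion
  with common random numbers, per-subject slopes, paired t-tests and
  Bonferroni adjustment.
* **behavior** — two-compartment zone-occupancy percentages
  (time-weighted) and pupil responses (mean baseline-z during the 10-s
  stimulus window).
* **pipeline** — seeded end-to-end orchestration of the intensity-series
  experiment and the ramped/damped envelope comparison, with every
  intermediate artifact serialised (CSV/JSON/HDF5).

## CLI

```bash
# write a config
python - <<'EOF'
from photodyn import io
from photodyn.pipeline import RunConfig
io.dump_yaml(RunConfig(seed=7, n_subjects=9, B=999).to_dict(), "run.yaml")
EOF

photodyn simulate   --config run.yaml --out sim/        # schedule + trace CSVs
photodyn preprocess --trace sim/trace_s00.csv --schedule sim/schedule.csv \
                    --rate 120 --out aligned.h5
photodyn metrics    --aligned aligned.h5 --schedule sim/schedule.csv --out metrics.csv
photodyn trend      --metrics metrics.csv --measure min --response average \
                    --B 10000 --seed 7 --level 0.95
photodyn behavior   --track track.csv --layout zones.json \
                    --sessions '{"s1": [0, 600]}' --out occ.csv
photodyn run        --config run.yaml --out results/    # full experiment
photodyn rampdamp   --config run.yaml --out results_rd/ # envelope comparison
```

## File formats

* schedule CSV: `trial_index,onset_s,intensity_db,envelope` (+ sidecar
  JSON with burst timing/envelope parameters)
* trace CSV: `time_s,value`; track CSV: `t_s,x_cm,y_cm`; pupil CSV:
  `t_s,area_px2`
* aligned tensors: HDF5 with datasets `z`, `rel_time`, `intensity` and a
  `rate` attribute
* zone layout JSON: `{"zone_a": [x0,y0,x1,y1], "zone_b": [...]}`

## A note on the z-unit convention of the generator

Per-trial z-scoring divides by the measured baseline standard deviation,
so kernel amplitudes specified "in z units" survive the pipeline only if
the simulated baseline has unit sd. When `noise_sd > 0` the generator
therefore adds a slow band-limited sensor fluctuation with complementary
variance (total baseline sd = 1); `noise_sd` is then the white-noise
fraction, and configured amplitudes (dip slope, transient height) come
out of the analysis on the intended scale.
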