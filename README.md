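# psrscreen

Phase-space-image analytics for subcutaneous ICD (S-ICD) vector screening.

## The problem

An S-ICD senses a surface-like ECG through up to three sensing vectors.
Whether a vector is usable hinges largely on its **T:R ratio** — the
T-wave peak amplitude divided by the R-wave peak amplitude.  When the T
wave sits too high relative to R, the device can double-count T waves as
R waves (T-wave oversensing), the leading cause of inappropriate shocks.
Standard screening uses a few seconds of ECG, but T-wave morphology is
dynamic — posture, rate, electrolytes — so a vector that passes a brief
screen can still oversense later.  Screening over many hours needs
automation: this package analyses long two-channel Holter recordings
(500 samples/s) the way the published deep-learning screening tool does,
and is aimed at device-clinic researchers studying eligibility dynamics.

## The method

1. **Segmentation** — each sensing vector is split into 10 s segments.
2. **Phase-space reconstruction (PSR)** — each segment x(t) is plotted
   against a delayed copy x(t − τ) (default τ = 20 ms) and the point
   cloud is rasterised onto a 32 × 32 grid of normalised visit counts.
   The time axis disappears; repetitive beat morphology becomes a
   compact attractor image (a sine wave becomes a circle).
3. **Convolutional regression** — a small CNN (two conv–pool feature
   blocks, dense 64 → 16 → 1, softplus output, squared-error loss) maps
   each PSR image to its T:R ratio.  A signal-domain peak-detection
   oracle provides labels and an independent baseline.
4. **Screening statistics** — per vector: mean T:R, SD, counts of
   segments over/below the eligibility cutoff (1:3), and

   FRT (%) = 100 · (10 s segments with T:R below cutoff) / (all segments),

   the *favorable ratio time*.  From simulator-style per-interval vector
   scores: EVT (%) — the *eligible vector time*, the percentage of
   assessments with a passing score.
5. **Correlation** — Spearman's rank test on three pairs:
   (mean T:R + SD) vs (mean score + SD), (mean T:R + SD) vs EVT, and
   FRT vs EVT.

Because no patient recordings are distributable, the package includes a
seeded synthetic Holter generator (sum-of-Gaussians beats, piecewise
regimes of amplitude/rate/noise/baseline wander) with exact per-segment
T:R ground truth, plus a monotone surrogate "simulator" producing vector
scores — every stage is testable end to end without any data download.
The published study's per-vector results table (14 patients × 2
vectors) ships as a checksummed CSV fixture for exact reproduction of
its summary statistics and correlations.

## Worked example

```python
from psrscreen import (generate_recording, generate_simulator_series,
                       segment_recording, oracle_series,
                       summarize_vector, compute_evt)
from psrscreen.workflows import ramp_schedule

# 10 min, two vectors: alternate drifts into unfavourable T:R territory
schedules = {
    "primary":   ramp_schedule([0.15, 0.20, 0.25], step_s=200),
    "alternate": ramp_schedule([0.25, 0.38, 0.45], step_s=200),
}
rec, truth = generate_recording(schedules, duration_s=600, seed=1)

for label in rec.vector_labels:
    segs = segment_recording(rec)[label]
    summary = summarize_vector(oracle_series(segs))
    evt = compute_evt(generate_simulator_series(truth[label], interval_s=60))
    print(f"{label:9s} mean T:R {summary.mean_tr:.3f}  SD {summary.sd_tr:.3f}  "
          f"over/below {summary.n_over}/{summary.n_below}  "
          f"FRT {summary.frt_pct:.2f}%  EVT {evt.evt_pct:.2f}%")
```

prints

```
primary   mean T:R 0.200  SD 0.041  over/below 0/60  FRT 100.00%  EVT 100.00%
alternate mean T:R 0.360  SD 0.084  over/below 40/20  FRT 33.33%  EVT 30.00%
```

The primary vector stays below the 1/3 cutoff in all 60 segments
(FRT 100%), while the alternate vector spends two thirds of the
recording above it (FRT 33.33%) and passes only 30% of the one-minute
simulator assessments — it would be the wrong vector to programme.

A `psrscreen` console command exposes the same workflow
(`simulate`, `train`, `predict`, `summarize`, `correlate`,
`reproduce-study`); see `psrscreen --help`.

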