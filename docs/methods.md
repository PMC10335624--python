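# Methods

## Synthetic Holter model

The generator emulates what matters for T:R screening — controllable,
time-varying T and R amplitudes in long two-channel recordings — and
nothing more.  One cardiac cycle is a sum of five Gaussian bumps
(P, Q, R, S, T); amplitudes, centres and widths are parameters, so the
noise-free T:R ratio of a beat is exactly `t_amp / r_amp`.  Defaults
(1 mV R, 60 beats/min, 0.10 mV P, −0.05/−0.08 mV Q/S, T centred 0.50 s
into the beat with 0.05 s width) describe an unremarkable adult beat and
remain valid to ~90 beats/min; beyond that the fixed T position no
longer fits inside the beat and construction fails loudly rather than
silently distorting.  The Q and S flanks are kept narrow (8 ms) so their
tails do not measurably pull down the R peak.

Time variation is a piecewise schedule of regimes: each regime fixes a
beat parameter set plus an additive white-noise SD and a sinusoidal
baseline-wander amplitude/frequency (default 0.33 Hz, respiration-like).
These two artefacts are the dominant Holter corruptions worth modelling
here.  Ground-truth labels — one T:R per whole 10 s segment, the regime
active at the segment midpoint — are fixed *before* noise is applied.
A master seed is split into independent per-channel streams, so the two
vectors carry independent noise but the whole recording is reproducible
bit for bit.

What the generator deliberately does **not** emulate: conduction
abnormalities, arrhythmia, ectopy, electrode motion artefact, QT-rate
adaptation, or any morphology change that is not an amplitude/rate/noise
regime switch.  Passing tests therefore demonstrate that the pipeline
recovers known T:R structure from clean-to-moderately-noisy periodic
signals; they do not certify performance on pathological human ECG.

The surrogate simulator maps each assessment interval's mean T:R
through a monotone-decreasing score function (default `1000·(1 − x)`,
clipped at zero) plus optional Gaussian noise; an interval passes when
its score meets the pass threshold.  The default threshold is the score
at T:R = 1/3, aligning "passing" with the screening cutoff.  This is a
gold-standard stand-in with known structure (zero noise gives Spearman
ρ = −1 against truth), not a model of the proprietary device algorithm,
whose score computation is out of scope and consumed as data only.

## Imaging

Segments are half-open 10 s windows; a trailing partial segment is
dropped, so a recording's segment count is `floor(duration / 10 s)` —
recording durations are treated as data, not constants.  The delay
embedding pairs each sample with the sample one lag earlier
(x = current, y = delayed); the default lag of 20 ms (10 samples at
500 Hz) is small against QRS width, keeping the fast limb of the
attractor open.  Rasterisation uses per-segment robust bounds (1st–99th
amplitude percentiles, clamped) so single-sample spikes cannot set the
scale and the image is exactly invariant to overall signal gain; scaled
coordinates are snapped to 10⁻⁹ of a pixel before flooring so that bin
assignment cannot flip under floating-point rounding of an amplitude
rescale.  Intensities are visit counts normalised by the maximum count
(grayscale, preserving dwell time) rather than binary occupancy.  A
constant segment (zero amplitude range) lights the single centre pixel.

## T:R estimation

**Oracle.**  R peaks: `scipy.signal.find_peaks` with height 0.7 × the
segment maximum and a 250 ms refractory distance — 0.7 because T:R can
reach 0.6, and a 0.5 threshold would catch tall T waves as R.  Baseline
is the lower quartile of the segment (the median sits too high when
waves occupy most of the beat at faster rates).  T amplitude: largest
absolute deflection 150–450 ms after each R; the estimate is
median(T)/median(R) over beats, robust to one truncated window at a
segment edge.  A segment with fewer than two detectable beats raises a
quality error, or yields NaN in batch mode; NaNs are excluded from
downstream statistics and counted.

**Convolutional regressor.**  Input 32×32 grayscale, two feature blocks
(3×3 convolution, ReLU, 2×2 max-pool; 8 then 16 filters), flatten,
dense 64 → 16 → 1, softplus output (T:R is non-negative), squared-error
loss, Adam at 10⁻³, 30 epochs, batch 32.  The network is written
directly on numpy arrays (im2col convolution, explicit backward passes)
and is sized to train in well under a minute on one CPU for the corpus
sizes used here.  All randomness — initial weights, batch order — flows
from one integer seed.  Predictions are clipped to [0, 1.5]: T can
exceed R pathologically, but an unbounded head is rejected for
stability.  Train/validation splits are by recording, never by segment,
to avoid leakage between adjacent segments.  Problem sizes used by the
tests and the acceptance script: 800 segments (five 800 s two-vector
recordings, T:R regimes spanning 0.05–0.55, varied R amplitude and
heart rate), one recording held out — held-out MAE lands near 0.01–0.02
with rank correlation above 0.99.

## Screening statistics

The eligibility cutoff is stored as the exact fraction 1/3 ("1:3" is
the quoted rule, not 0.33).  "Below" is strict; a segment exactly at
the cutoff counts as over-threshold — the conservative reading for
eligibility — and the cutoff is configurable.  FRT is reported to two
decimals; full precision is kept internally.  Group summaries report
both spread conventions — sample SD (n−1) and the normal 95% CI
halfwidth 1.96·SD/√n — because the study's own "±" values mix them:
its subgroup spreads match CI halfwidths while its combined T:R/SD/FRT
spreads match sample SDs.  Reports label which convention each number
uses.  A paired two-sided Wilcoxon signed-rank test is provided for
group contrasts as a descriptive convenience; its p-values are not
reproduction targets because the study does not name its test.

## Correlation

Spearman's coefficient is computed from first principles — average
ranks for ties, Pearson correlation of the rank vectors — with a
two-sided t-approximation (n − 2 df) p-value and an optional seeded
permutation p for small n; the implementation is verified against an
independent reference in the tests, never replaced by it.  The three
variable pairs read "mean + SD" literally as the arithmetic sum of the
two columns (it is the x-axis of the study's scatter plots).  Signed
coefficients are kept alongside magnitudes: on the study table the two
T:R pairs are negative (favourable T:R is low, favourable score high)
and FRT-vs-EVT is positive, while the study prints magnitudes, so
acceptance is on |ρ|.

## Reproduction scope and known discrepancies

All 28 FRT values, all graded group means, and the FRT-vs-EVT
correlation (computed 0.65295 vs printed 0.652, which appears
truncated; agreement is assessed within one unit of the last printed
digit) reproduce from the packaged table.  Two printed results do
**not** reproduce from the study's own rows and are reported as
computed: the first two correlation magnitudes (printed 0.636 and
0.668; the table yields 0.550 and 0.597 under every pairing
orientation we tried, suggesting they were computed on undeposited
full-precision values) and the subgroup means of the score-SD column
(printed 95.23/160.56; the table's rows give 209.98/45.81, and the
prose direction contradicts the table).  The reproduction report marks
these FAIL rather than adjusting anything.

## End-to-end design choice

A rank correlation needs at least three paired observations, but a
single two-vector recording yields two.  The end-to-end check therefore
screens one held-out vector in twelve 5-minute blocks engineered to
have twelve distinct below-cutoff fractions, with every segment's T:R
kept far from the cutoff (0.10 or 0.55) and the surrogate assessed at
10 s intervals: block FRT from model predictions then equals block EVT
from the zero-noise simulator exactly, and their Spearman |ρ| is 1.

## Limitations

Heart rates above ~90 beats/min need user-supplied wave timing; the
oracle assumes upright R peaks and a 150–450 ms T window, so inverted-R
morphologies or extreme QT values would need reconfiguration; the CNN
is trained per-corpus, and no pretrained weights are shipped (the
original tool's weights are unavailable); heavy baseline wander biases
the oracle's T measurement, which is why training labels come from
noise-free ground truth rather than the oracle under artefact.
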