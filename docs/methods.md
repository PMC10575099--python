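# Methods

## The measurement and the model chain

A wearable bioimpedance analyzer excites the fish at eight frequencies
(30–100 kHz, 10 kHz apart) and returns the real part `R` and imaginary part
`I` of the transfer signal per frequency, together with temperature.
Magnitude and phase are `M = sqrt(R^2 + I^2)` and `theta = arctan(I/R)`;
because only the ratio `I/R` enters, the phase is a principal value in
(−π/2, π/2] and quadrant information is not recoverable — a limitation of
the measurement, recorded rather than repaired. Calibration against a known
resistor gives a per-frequency gain `K = 1/(M_ref * R_ref)` and impedance
`Z = 1/(M K)`; the gain is per frequency because analog front-end gain is
frequency dependent even though the calibration relation itself is not.

Downstream, the chain is: gross-error rejection → least-squares smoothing →
checkpoint completion → GRA stress weighting → MIC feature screening →
two-stage recurrent stress estimation → weighted total stress → Z-shaped
fuzzy health mapping and discrete classification. Each stage is usable on
its own; the pipeline driver only sequences them.

## Gross-error rejection (Romanovsky criterion)

For a series of `n` samples, the suspect with the largest absolute deviation
from the mean of the *remaining* samples is removed when the deviation
exceeds `K(n, alpha) * sigma`, where `sigma` is the standard deviation of
the remaining samples with an `n − 2` divisor, and the pass repeats on the
shortened series.

The test coefficient is `K(n, alpha) = t_{1 − alpha/(2n), n−2}` — the
two-sided Student-t quantile with a Bonferroni share of `alpha` per
candidate suspect. The correction is load-bearing: the tested deviation is
the *maximum* of `n` deviations, so an uncorrected per-sample quantile
(`t_{1 − alpha/2}` ≈ 2 at alpha = 0.05) rejects roughly `alpha` of clean
Gaussian data on every pass, the spread estimate shrinks, and the iteration
cascades to ~17% removal on clean data; the corrected coefficient keeps the
whole iterated filter's false-rejection probability near `alpha` (measured
~2·10⁻⁴ of samples at n = 200) while a 10-sigma spike exceeds the threshold
by a wide margin. A zero `sigma` with a nonzero deviation removes the
suspect (any deviation from an otherwise constant series is gross).

Trending sweep channels are first detrended with an 11-point rolling median
(robust to the spikes being hunted) and the filter is applied to the
residuals; flagged samples are replaced by linear interpolation so the
channel keeps one row per timestamp. Default `alpha` is 0.05 everywhere.

## Smoothing and checkpoint completion

Savitzky–Golay smoothing uses a half-width `w = 5` (11-point window) and
order 3 by default — wide enough to suppress the sensor noise floor without
flattening the logistic stress transition at 5-minute sampling; both are
configuration. Edges are evaluated from the polynomial fitted to the
terminal window. Sparse biomarker checkpoints (hourly in the emulated
design) are completed to the sweep grid with a natural cubic spline; queries
outside the checkpoint range raise rather than extrapolate, because the
spline's cubic tails are uninformative about future stress.

## GRA weighting

Stress factors and nutrient series are min-max normalized per series (a
constant series maps to 0.5; initial-value normalization was rejected
because pH is near-constant and would blow up). Each nutrient serves as the
reference series in turn; deviations' extrema are taken jointly over the
three stress comparisons per reference (the standard GRA convention — the
alternative per-series extrema would make every factor's best coefficient
exactly 1). The resolution coefficient defaults to ρ = 0.5, the
conventional midpoint of its (0, 1) range. A factor's relational grade is
its coefficient mean over time and references; weights are grades normalized
to sum 1. When no nutrient panel is available the pipeline substitutes the
reference study's published allocation (lactate 0.396, glucose 0.290,
cortisol 0.314) and logs the substitution; those constants are honored as
given, since the panel data behind them are not public.

## MIC screening

`MIC(x; y)` maximizes `I(X;Y)/log2(min(cols, rows))` over grid partitions
with `cols · rows ≤ B`. One axis is binned (equipartition by rank, ties kept
together); the other is optimized *exactly* by dynamic programming over
candidate cut positions, for every admissible bin count; both orientations
are searched. For n ≤ 16 every distinct-value partition of the binned axis
is enumerated, which makes the search provably exhaustive — the regime used
to check the implementation against an independent all-partitions brute
force. For larger n the candidate cuts are thinned to at most 64
equipartition positions.

Two bound rules are exposed. The default, `B = 0.6 n`, follows the original
monitoring design and is appropriate for screening near-noiseless
stress-coupled channels (coupled channels score ≥ 0.99, uncoupled ≈ 0.37 at
n = 200). Under independence, however, a bound linear in `n` keeps the grid
resolution growing as fast as the data and the plug-in normalized MI does
not converge to zero — its null median at n = 200 is ≈ 0.36. Null-calibrated
analyses should use the sublinear literature rule `B = n^0.6` (null median
≈ 0.17 at n = 200); the package's null-distribution test does. A feature is
selected when MIC ≥ 0.9 for *every* stress factor (an any-factor switch is
provided); selection preserves (channel, frequency) order.

## Stress estimation

Windows of length 15 over the screened features plus temperature predict the
target `horizon` steps past the window end; features and target are min-max
scaled with scalers retained for exact inversion. Stage one is a 1-D CNN
(one layer, kernel 3, 16 channels, ReLU — the smallest architecture that
fulfils the feature-extraction role; all exposed) feeding a stacked LSTM
(2 × 32 by default) with additive attention (`e_j = v·tanh(W h_j + U q + b)`,
softmax weights, last hidden state as query) and a small dense head. Stage
two regresses the *training-set* residuals of stage one — never validation
residuals, to avoid leakage — with a bidirectional GRU (2 × 32) plus its own
attention head and a three-layer dense stack; the final prediction is the
stage sum. The 80/20 split is chronological, not shuffled, because the
targets are trends. Training is minibatch Adam on MSE (batch 32, default
200 epochs with patience-20 early stopping on the training loss); a NaN loss
raises with the config echoed. A zero-span (constant) target short-circuits
to an exact constant predictor.

All networks run on a compact reverse-mode autodiff core over numpy arrays
written for this package (`_autograd.py`); its gradients are verified
against central finite differences in the test suite, and the trainable GRU
layer is cross-checked against the plain-numpy `gru_step`/`bigru_encode`
primitives.

95% forecast bands are `point ± 1.96 · s` with `s` the RMS validation
residual (the second moment about zero, not about the mean): systematic
validation bias then widens the band, which is what makes the band honest
for a chronologically split trend — measured ground-truth coverage on
simulated runs is ≈ 93% pooled over seeds.

## Health mapping and classification

The health score of a nutrient panel at time `t` is the mean of the min-max
normalized nutrient values with every analyte oriented so the fresh (t = 0)
state maps to 1 — rising analytes such as muscle lactate are flipped. The
orientation (fresh = 1, depleted = 0) is required for consistency with the
published level table, whose strong-live-level score range is [1, 0.857).

Total stress is the weight-normalized sum of min-max scaled factors, clipped
into [0, 1]. The Z-shaped membership function is 1 below `a`, 0 above `b`,
with two quadratic arcs joined at the midpoint; the zone coefficients
(a = 0.019 at 1–3 °C, a = 0.0138 at 3–6 °C, b = 1) are shipped defaults.
Envelope fitting recovers `a` from (stress, score) points as the mean of the
tightest curve above all points (smallest such `a`) and the tightest curve
below them (largest such `a`), each found by monotone bisection; if every
candidate encloses the points the search-interval midpoint is returned with
a warning. Note that scores clipped to exactly 0 below the curve's support
make a strict lower envelope unattainable — recovery experiments therefore
sample the informative mid-branch of the curve.

Discrete levels use zone-specific average-stress breakpoints (left-closed,
right-open, matching the published interval notation). The breakpoints are
configuration, not recomputed: they are not reproducible from the membership
function with the shipped coefficients, so they are treated as given
empirical constants. The averaging window for the assessed stress defaults
to everything since monitoring start. The near-death point is the first
observation checkpoint with survival below 60% (threshold exposed).

## The synthetic-data generator

The generator emulates the monitored experiment: an 84-hour waterless run
sampled every 5 minutes, two temperature zones (1–3 °C and 3–6 °C), hourly
biomarker checkpoints and 6-hourly nutrient panels with ~1.5%-of-range assay
noise. Stress factors follow logistic (saturating-growth) trajectories —
glucose 3→9 mmol/L, lactate 2→14 mmol/kg, cortisol 20→180 ng/mL, with
zone-dependent rates (0.08/h vs 0.12/h; the warmer zone rises strictly
faster) and mild per-run jitter; a smooth saturating family was chosen over
empirical curve shapes so that spline completion and estimation have a
well-defined ground truth. Nutrients decay exponentially toward a floor;
muscle lactate mirrors the stress lactate. Impedance magnitude at the
coupled frequencies (70–100 kHz by default) is baseline plus 80 Ω times the
normalized mean stress — an SNR of 40 against the 2 Ω channel noise;
uncoupled channels are constant plus noise. The *sign* of the
stress-impedance coupling (impedance rises with stress, consistent with
dehydration raising tissue impedance) is a simulator convention, not a
biological claim — the source design never states it. Gross errors are
isolated single-sample spikes of exactly ±10 noise-sigma replacing the
Gaussian noise at their sample (so every recorded spike deviates from the
noiseless value by exactly 10σ), at rate 0.002 per sample per channel, with
positions recorded.

Mortality has two modes: a deterministic fixture replaying the observed
25-fish cohort (2 dead at 60 h, +3 at 72 h, +3 at 78 h, +3 at 84 h —
survival 56%, near-death point 84 h) and a seeded random mode with a
logistic-in-time per-fish death probability, zone-shifted and scaled by a
hazard factor (0 disables mortality).

What the generator does *not* emulate: electrode-contact drift, baseline
wander, Cole–Cole dispersion across frequencies, fish-size covariates, or
oxygen depletion. Passing tests therefore demonstrate that the chain
recovers known structure under Gaussian noise, isolated spikes and smooth
monotone physiology — not that it is robust to every artifact of a live
deployment.

## Problem sizes and numerical choices

Validation experiments run at CI scale by the package's own choice: the
model-ranking experiment uses 140-point series with AR(1) residual
structure (φ = 0.85), 10 seeds, compact widths (hidden ≈ 8–10) and 40
epochs; band coverage uses 24-hour simulated runs over 20 seeds; gross-error
recovery uses 50 full-length runs; MIC oracle equivalence uses 50 random
series of length 8–12 with B ≤ 16. Tolerances: calibration round-trips to
float precision; ZMF branch joints are continuous to 1e-12; envelope
bisection to 1e-9 (recovery asserted to 1e-6); MIC-vs-oracle agreement to
1e-9. Ties in rank-based binning keep equal values in one bin. MAPE is
reported as a fraction, not a percentage, and requires strictly nonzero
truths. Macro metrics give empty predicted classes a 0 contribution with a
logged warning (the scikit-learn convention); micro precision/recall/F1
equal accuracy for single-label multi-class input and the implementation
asserts that identity exactly.

## Known limitations

- Real WBIA + biomarker data are not bundled; all performance figures are
  on synthetic conditions with known ground truth.
- The phase quadrant is unrecoverable from `I/R` by construction.
- The published level breakpoints and weight allocation are honored as
  constants rather than re-derived; nothing in the package can validate them
  against their original cohort.
- Multi-horizon forecasts train one model per horizon; no recursive or
  sequence-to-sequence decoding.
- MIC under the default linear bound rule is not null-calibrated; use the
  `n^0.6` rule for independence testing.
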