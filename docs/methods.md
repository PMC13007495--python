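# Methods

This note documents the models, numerical choices and limitations behind
`proteodyn`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Signals and preprocessing

A recording is a set of uniformly sampled differential voltage channels
(default eight, labelled ChA–ChH) in millivolts, with an optional
stimulus-input channel carried in volts and excluded from mV-domain
metrics. The sampling rate is a required input and is never inferred:
recordings in this domain exist at both 1 Hz (multi-day spontaneous
monitoring) and 1 kHz (stimulus-locked acquisition), and a supplied rate
that disagrees with an explicit time column by more than 0.1% is a hard
error rather than a silent correction.

Before phase analysis, channels are detrended with a zero-phase
(forward–backward) 2nd-order Butterworth high-pass at 0.0001 Hz. The
filter family and order are implementation choices — what matters
downstream is zero phase distortion, since instantaneous phase is
extracted next. Whether the high-pass should also precede the complexity
metrics is left configurable (`apply_highpass`); complexity is computed on
mean-thresholded windows and is offset-invariant, so the choice matters
only when drift within a single window is large.

Stimulus-locked transients are handled by masking the first 10 s after
each optical pulse. Windows overlapping a masked gap are dropped, never
shortened or imputed, so every retained window carries the same number of
samples and the windowed statistics stay comparable.

The running-median baseline (default 10,000-sample window) uses shrinking
windows at the edges rather than padding; padding would fabricate data at
exactly the places where drift estimates are least constrained. Slope
estimation uses the analytic derivative of the local 5-point, order-2
Savitzky–Golay polynomial scaled by the sampling interval; the reported
rate-of-change is the maximum absolute smoothed derivative, which equals
the maximum over any sliding-window partition of it.

## Complexity metrics

Windows (default 1000 samples advancing by 100) are binarized at their own
mean with a strict `>`, so ties map to 0 and an all-equal window yields an
all-zero sequence flagged degenerate. The phrase count `c(n)` is the LZ76
exhaustive-history production parse — each phrase is the shortest
extension not reproducible by copying from anywhere in the prior history.
The implementation uses a binary search over reproducible prefix lengths
with C-speed substring search; tests verify exact agreement with a
brute-force parser that simulates the copy process explicitly.

Two normalizations of the same count are always reported:
`c(n)·log2(n)/n` (primary; the finite-length bound normalization under
which fair-coin sequences score ≈1) and `c(n)/(n·log2 n)` (secondary;
kept for comparability with the alternative rendering of the formula).
They differ by the factor `(log2 n)²`. Note that with binary windows of
N = 1000, the primary normalization is bounded by `log2(1000) ≈ 9.97`
and in practice sits near 1; published summary values far above that
range cannot be produced by either formula at this window length and are
not a target of this package.

Permutation entropy uses order m = 3 (6 ordinal patterns) at embedding
delay 1; the delay is configurable since the trade-off between temporal
resolution and pattern diversity is data-dependent. Ties within a pattern
are broken by order of occurrence (stable sort), the common Bandt–Pompe
convention. The statistic is invariant under strictly monotone transforms
of the window, which the tests exercise directly.

## Coherence and networks

Instantaneous phase is the angle of the analytic signal (Hilbert
transform) per channel. The pair PLV is computed in the order: time
average of the unit phasor of the phase difference, then modulus, then
(for `I_sync`) the average over all unordered pairs — this ordering is what
guarantees `0 ≤ I_sync ≤ 1`. Under independence the pair PLV concentrates
at `√π/2 · T^(−1/2)` (Rayleigh statistic), which the null-calibration
tests verify within 20% at T = 1000.

Adjacency uses the 75th percentile of the window's 28 PLVs as threshold
θ_w, with linear interpolation between order statistics (so θ_w is
bit-reproducible) and a strict `>` comparison. On distinct values this
retains 7/28 = 25% of edges; tied data can retain fewer, which is
reported, not corrected. A robustness helper re-thresholds at the
70th–80th percentiles, and a weighted-efficiency companion uses `1/W_ij`
as edge length on the full PLV graph.

Graph metrics are delegated to networkx behind the module surface:
BFS all-pairs shortest paths with disconnected pairs contributing 0 to
global efficiency, and mean local (Watts–Strogatz) clustering with
`C_i = 0` for degree < 2. Both are verified against exhaustive
enumeration oracles on 500 random graphs of up to 8 nodes — at that size
the brute-force check is complete, not sampled.

## Dual-regime classification

Two classifiers are emitted side by side, since they answer slightly
different questions and no reconciliation rule is defined:

**Fit route.** Peaks are local maxima exceeding two SDs above a
10,000-sample moving average (adjacent super-threshold samples collapse
to their run's maximum). The subsequent decay segment (default 1000
samples, truncated at the next peak) is fitted with `V0·e^(−t/τ)`
(nonlinear least squares, initialized from the log-linearized slope, τ
bounded to the segment span) and `V0 + A·log t` (linear in ln t; natural
log, as forced by the characteristic time `t_c = e^(−V0/A)`). The winner
by R² supplies the timescale; τ < 600 s labels Regime I, τ > 3600 s
Regime II, in between transitional — a partition, verified property-wise.

**Window route.** Per channel, window σ_V is compared against its 60th
percentile (per-channel by default; the percentile base population is
configurable) and the autocorrelation 1/e decay time τ_AC (linear
interpolation between bracketing lags). Volatile windows need high σ_V
and τ_AC below threshold; the default τ_AC cutoff of 0.1 s presumes
kHz-scale sampling, so analyses at 1 Hz should pass a cutoff of a few
sample intervals (the synthetic-recovery tests use 2 s at 1 Hz).
Nonvolatile labelling requires a contiguous below-threshold run longer
than 10 h, plus — when stimulus events exist — a memory criterion: the
post-offset voltage returns to within 10% of the pre-stimulus baseline,
measured relative to the stimulus-driven excursion.

A structural caveat discovered while validating against generated ground
truth: because the σ_V threshold is a percentile of the same windows being
classified, it only separates volatile from quiet spans when both occupy
a comparable fraction of the recording. With, say, 95% plateau windows,
the 60th percentile lands inside the plateau's own σ distribution and no
long below-threshold run can exist. The bundled regime generator
therefore defaults to 10 h volatile + 11 h plateau — both regimes
expressible, the plateau still exceeding the 10 h persistence bound.
Strongly imbalanced recordings need either a different percentile or the
fit-based route.

Drift fitting selects between `V0 + A·log(t/t0)` and `V1 + B·e^(−t/τ2)`
per contiguous 10,000-s segment by AIC, using the least-squares form
`AIC = n·ln(RSS/n) + 2k` with k = 2 (log; t0 is fixed at 1 s because it
is jointly unidentifiable with V0 — shifting t0 only re-parameterizes the
intercept) and k = 3 (exponential). RSS = 0 maps to −∞ with an exact-fit
flag. The AIC constant term is irrelevant for within-segment comparison.

## Optical stimulation codec

Encoding: row-major flatten, `V = I/51` (0–255 → 0–5 V, 5/255 ≈ 0.0196 V
per intensity unit), one pixel per `dt` (default 1 ms). Decoding:
5th/95th-percentile normalization to 0–5 V with clipping, inverse ×51
map, clip to [0, 255], row-major reshape, then CLAHE (clip 2.0, 8×8
tiles). The percentile normalization is deliberately unit-free — it
absorbs gain and offset, so mV-scale potentials decode without an
explicit volt conversion, and the decode is invariant under affine
rescaling of its input (tested). CLAHE is a display-only, non-invertible
enhancement applied last and excluded from round-trip guarantees; the
pre-CLAHE raster is always emitted alongside. CLAHE is implemented with
scikit-image's adaptive equalization with the tile grid mapped to the
kernel size and the clip limit rescaled to its [0, 1] convention. The
decoder never resizes: supplying exactly rows×cols samples is the
caller's explicit responsibility.

## Synthetic generator

The generator's laws and default constants mirror the observed dynamics:
slow drift `V0 + A·e^(−t/τ1)` switching to `V1 + B·log(t/t0)` (defaults
V1 = −40 mV, B = 15 mV, t0 = 10⁴ s; transition at 4·10⁴ s; the
pre-transition amplitude A = 20 mV and τ1 = 5000 s are chosen as
representative of the initial stabilization phase); burst trains with
first interval 714 s shrinking geometrically to 580 s and first amplitude
7.9 mV decaying to 4.27 mV; damped harmonic transients in closed form
(verified against a high-accuracy ODE integration); diffusive coupling
integrated by fixed-step Euler–Maruyama at the sampling interval with an
explicit stability guard (`max total rate × dt < 1`) and a step-halving
convergence test; saturating relaxation with τ = 273 s as the default
stimulus kernel constant; additive white Gaussian noise, default 0.5 mV.
Branch continuity at the drift transition is not enforced — the two
branches are independent laws — and the jump magnitude is reported in the
ground truth. The intrinsic coupling dynamic g defaults to a linear leak
`−V/τ_leak`; the burst waveform is a raised-cosine pulse of configurable
width. The geometric interval law accumulates in finite time, so trains
stop once the interval falls below one sampling interval.

What the generator does **not** emulate: electrode drift and contact
artifacts, 50 Hz interference, non-Gaussian noise, genuine electrochemical
nonlinearities, and cross-channel propagation delays. Passing
parameter-recovery tests on this generator therefore demonstrates the
correctness of the estimators under the stated models, not robustness to
every laboratory artifact.

## Problem sizes and determinism

Monte-Carlo checks use 50 seeds for decay recovery and drift selection,
100 for complexity calibration and correlation recovery, 200 for the PLV
null, 500 random graphs for the network oracle, and 20 generated
recordings for regime-label recovery; per-run problem sizes (500–10,000
samples per fit, 21 h regime recordings at 1 Hz) are chosen so each suite
completes in seconds on a single CPU while keeping estimator standard
errors well inside the asserted tolerances. All randomness flows through
`numpy.random.default_rng` seeds carried in the specs; identical
configuration (including seed) reproduces any recording and any pipeline
bundle byte-for-byte.

## Known limitations

- The window-rule σ_V percentile threshold is relative to the analyzed
  recording (see above); it is not an absolute volatility scale.
- The decoder's CLAHE step differs numerically from other CLAHE
  implementations; only the pre-CLAHE raster is guaranteed reproducible.
- Exponential decay fits on segments much shorter than τ are weakly
  identified; the fitter bounds τ generously and reports R², but segment
  length should be matched to the expected timescale.
- No statistical null models beyond the random-phase PLV baseline are
  provided; persistence of synchronization across non-overlapping windows
  is exposed as a descriptive comparison, not a hypothesis test.
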