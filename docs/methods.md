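# Methods

This note documents the models, estimators and numerical choices behind
`circaquant`, the assumptions they rest on, and what the package's
simulation-based validation does and does not demonstrate.

## The measurement model

A whole-slice bioluminescence trace is modeled as

    y(t) = B(t) + A·e^(−t/τ)·cos(2π(t − φ)/P) + ε(t) + spikes,

with `B(t) = B₀·e^(−t/τ_B)` a slow monoexponential baseline (media and
substrate depletion), `A` the oscillation amplitude, `τ` a damping time
constant (tissue-level desynchronization, not single-cell amplitude
death), `P` the free-running period, `φ` the time of the first peak,
`ε ~ N(0, σ²)` photon/read noise, and rare single-sample positive spike
artifacts. An image stack applies the same oscillator to every in-tissue
pixel, giving each cell-scale region its own fixed phase offset.

The analysis chain never fits this model directly; it uses
model-agnostic steps (rolling means, periodograms, sliding-slope peak
calling) so that it behaves sensibly on real traces that violate the
model in unknown ways.

## Trace preprocessing

**Windows in samples.** A window of `w` hours centered at a sample
includes every sample within ±w/2 h inclusive; at 10-min sampling a 2-h
window spans 13 samples, a 24-h window 145. Rolling means are centered
and truncate at the trace ends (no padding — padding invents data at the
boundaries of a finite recording).

**Aberrant-count filter** (`filter_aberrant`, defaults `window_h=2`,
`k=8`). The deviation scale is the mean absolute deviation of
(raw − 2-h smoothed); points whose deviation exceeds `k` times that
scale are replaced by linear interpolation between surviving neighbors
and flagged. Mean-absolute was chosen over RMS as the natural robust
scale for a spike test; both are exposed (`deviation=`). With a very
large spike the 2-h smoothed trace itself rises near the spike, so a
spike's immediate neighbors can also cross the threshold; they are then
interpolated too, which slightly smooths ~1 h of trace around each spike
and is harmless to period and amplitude estimates. The filter is
idempotent on the generator's spike model (verified in tests).

**Detrending** (`detrend`, default 24 h). The baseline is the centered
24-h rolling mean computed from *full* windows only. Within 12 h of
either end the truncated window no longer averages a whole cycle, so its
mean leaks the oscillation itself into the baseline; subtracting that
distorts the last/first half-cycle and measurably biases downstream
period estimates (≈ −0.2 h in our validation settings when the analysis
window touches the recording end). The baseline is therefore extended
into each edge region by a straight line fit to the adjacent 24 h of
interior baseline — exact for constant or linear drift, and with error
second order in the drift curvature over half a window (< 1 signal unit
for the drifts simulated here).

**Noise scale.** `trace_rmse` is √mean((detrended − smooth₂ₕ)²), both
operands on the detrended baseline. Taking the smoothed *raw* trace
instead would make the RMSE dominated by the trend; this reading keeps
it a pure noise scale. For white noise of sd σ it converges to
σ·√(1 − 1/13) at 10-min sampling (verified by simulation).

## Period and rhythmicity

`lomb_scargle` computes the classic variance-normalized Lomb–Scargle
power via `scipy.signal.lombscargle` on mean-centered values, over a
frequency grid from 1/32 to 1/16 h⁻¹. The grid spacing is
`min(1/(oversample·T), period_step/scan_max²)` with `oversample=10` and
`period_step=0.02 h`, so adjacent candidate periods differ by < 0.02 h
everywhere in the scan range regardless of window length. The scan range
16–32 h covers short-period mutant phenotypes while excluding the 12-h
harmonic.

The p-value is the analytic false-alarm probability of the tallest
peak: the single-frequency tail for variance-normalized power with
estimated variance, `(1 − 2z/(N−1))^((N−3)/2)` (→ e^(−z) for large N),
combined with the Baluev (2008) aliasing-free band correction
`FAP ≤ 1 − (1 − p₁)·e^(−τ)`, `τ = W·√z·p₁`, where `W` is the scanned
bandwidth times the effective window width √(4π·var(t)). Calibration
over 500 pure-noise traces gives empirical type-I rates of ≈0.018 at
α=0.01 and ≈0.05 at α=0.05 — within the binomial uncertainty of nominal,
slightly anti-conservative at the extreme tail where the single-peak
approximation is roughest. Per-pixel rhythmicity screening at α=0.01
therefore errs a few tenths of a percent liberal. A value-shuffling
permutation null (`n_permutations`) is available when the analytic
approximation is not trusted; circular shifts were rejected as a null
because they preserve a periodic signal's own structure and hence have
essentially no power against periodicity.

Interpolated (previously spike-flagged) points are included by default;
`exclude_interpolated=True` drops them, which Lomb–Scargle tolerates by
construction.

## Peaks, amplitude, half-life

**Sliding-slope peak calling.** At every sample, the slope of an 8-h
centered least-squares line of the 2-h smoothed trace; a +→− sign change
marks a peak, −→+ a trough. The crossing is located by linear
interpolation between the two bracketing slope samples, giving
continuous-time peak estimates — essential for imaging, where 1-h frames
would otherwise quantize peak times so coarsely that a phase-offset MAD
below the frame interval is unmeasurable (rounding a Laplace offset
population with MAD 0.85 h to a 1-h grid yields a MAD of exactly 1.0 h).
Zero-slope runs resolve to the run midpoint, ties toward the earlier
sample. An optional minimum same-type extremum spacing (half the minimum
scan period, used for per-pixel calling) collapses noise doublets,
keeping the more extreme member. Peaks index cycles (1-based); each peak
pairs with the next trough in time.

**Amplitude.** `(peak − trough)/RMSE` per cycle, dimensionless; an RMSE
at numerical zero is rejected rather than returned as an infinite
amplitude. Final-cycle amplitudes are compared across slices as
percentages of the control-group mean.

**Half-life.** The 12-h segment starting 2 h after cycloheximide is
min-max normalized to [0, 1] (segment boundaries carry a half-sample
tolerance so grid-aligned requests include their endpoints despite
floating-point drift) and fit by nonlinear least squares with
y = e^(−t/k), k seeded at 3; half-life = k·ln 2 exactly, with ln the
natural log (the mathematics of exponential decay). Min-max
normalization forces the segment to end at exactly 0, which the
asymptote-free model absorbs by decaying slightly fast: on a noise-free
pure exponential the fitted k is 0.9519× the true k (grid-search
verified, affine-invariant in t/k units), a ~4.8% systematic
underestimate of half-life shared identically by every trace analyzed
this way — group *comparisons* are unaffected. An offset-decay model
would remove the bias but is deliberately out of scope to keep the
procedure as simple and auditable as the one it mirrors.

## Imaging pipeline

Stacks are trimmed to a fixed frame count (pass-through with a warning
if shorter), denoised by a 2-frame pixelwise minimum (removes any
artifact present in exactly one frame; costs one frame and biases all
pixels' waveforms identically, so relative phase is untouched), and
sum-binned into 4×4 blocks (sum rather than mean preserves photon
statistics; every downstream phase measure is scale-invariant, so the
choice is cosmetic but documented). Partial edge blocks are dropped; a
binned pixel is kept when ≥ 50% of its source pixels are in-mask. Liver
recordings are analyzed unmasked by default; SCN recordings use a mask
drawn on the whole-recording mean projection (polygon, emulating a
manual outline, or intensity threshold).

The whole-slice frame-mean trace defines cycles via its own peak times.
Each binned pixel's trace is detrended and smoothed with the same
settings as whole traces, its peaks called with the same detector, and
each pixel peak assigned to the nearest whole-slice cycle (ties to the
earlier cycle; if several pixel peaks land in one cycle the nearest
wins). Relative peak time = peak time − mean peak time of all pixels in
that cycle, so the per-cycle mean is zero by construction. Phase
dispersion per cycle is the raw MAD (no 1.4826 consistency constant —
the quantity is reported in hours of spread, not as a Gaussian-σ
estimate); the per-slice summary is the mean of per-cycle MADs over the
first four cycles (a cycle average rather than a single cycle or pooled
peak times: the three readings are all computable, and the cycle
average is the default because it uses all cycles symmetrically).
Dispersion trajectories (MAD, or MAD − MAD₁, vs cycle) of two groups are
compared by an extra-sum-of-squares F test: reduced model = common slope
with per-group intercepts, full model = per-group slopes,
F = ΔRSS/(RSS_full/df). The implementation is verified against
statsmodels' nested-model ANOVA and calibrated by null simulation.

## Expression

Cosinor: OLS of y = M + β_s·sin(2πt/P) + β_c·cos(2πt/P) at fixed period
(default 24 h), requiring ≥ 4 distinct timepoints spanning ≥ half a
period. Amplitude = √(β_s² + β_c²); acrophase = (P/2π)·atan2(β_s, β_c)
mod P, the hour of the fitted maximum. Replicates are fit as individual
points, group-wise.

ΔΔCt: per sample, ΔCt = Ct_gene − Ct_housekeeping; ΔΔCt = ΔCt − mean
reference-group ΔCt per gene; fold = 2^(−ΔΔCt). Fold changes are
summarized as the mean of per-sample folds (matching how such values
are conventionally graphed), so the reference group means exactly 1.
Samples missing a housekeeping Ct are excluded with a warning. No
primer-efficiency correction is applied.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the estimators
assume: damped cosines on monoexponential drift, Gaussian read noise,
Poisson-placed single-sample spikes sized as a multiple of the local
deterministic level, exponential decays, and image stacks whose phase
offsets are drawn once per 4×4 pixel block from a zero-median Laplace
distribution. Laplace was chosen over Gaussian because its population
MAD equals the scale times ln 2 exactly, making MAD-recovery targets
exact in expectation; offsets are drawn at the block (cell) scale
because tissue phase is coherent over cell-sized domains — and because
4×4 binning of 16 independent offsets would average the dispersion away,
which is not how cellular desynchrony behaves. Dispersion growth
rescales each block's fixed offset per cycle (coherence loss preserving
rank order, not re-randomization), with cycle boundaries placed at
troughs so peaks never straddle a boundary. Hot pixels are single-frame
by construction. All randomness flows from one integer seed per call
through independent child streams (noise, spikes, offsets, hot pixels),
so tests can regenerate any ingredient alone; identical seeds give
bit-identical output.

Default levels — noise 10% of amplitude for traces, 20% per raw pixel
(5% per binned pixel) for stacks, 0.25 spikes/24 h, baseline 3× the
amplitude decaying with τ_B = 72 h — are plausible for healthy slice
recordings but are not calibrated to any instrument's measured noise
spectra. Passing the recovery suite therefore shows the estimators are
correct and unbiased *under this model*; it does not certify accuracy on
recordings with structured artifacts (focus drift, media changes,
movement) that the generator does not emulate. The generator also omits
spatial coupling between regions and camera-specific noise beyond
Gaussian read noise and hot pixels.

## Validation problem sizes

The recovery experiments (`circaquant.validation`, mirrored in
`tests/test_acceptance.py` and `scripts/acceptance.py`) use 10 traces
per condition (168 h or 144 h at 10-min sampling) and single 180×180
stacks of 110 hourly frames yielding 2025 binned pixels over 4 cycles —
sizes at which the mean period estimate is stable to a few hundredths
of an hour and the sample MAD of ~2000 Laplace draws to a few
hundredths of an hour, comfortably inside the ±0.1–0.15 h acceptance
tolerances. Null calibrations use 500 noise traces (rhythmicity) and
200 simulations (slope F test).

## Known limitations

- The analytic FAP is an approximation; at α ≤ 0.001 prefer the
  permutation null.
- The half-life estimate carries the ~4.8% normalization bias described
  above.
- Peak calling assumes one peak per cycle per pixel; multi-modal
  waveforms within a cycle are resolved to the nearest-cycle peak only.
- No image registration or cell segmentation: binned pixels are
  cell-scale regions, not cells.
- Period estimates assume the detrended rhythm is stationary in
  frequency across the analysis window; a drifting period returns a
  power-weighted compromise.
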