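# Methods

## Scope and data model

`caflux` analyzes per-cell fluorescence time series from time-lapse calcium
imaging of dissociated embryonic neural cells, together with per-cell FISH
mean intensities and an ROI co-registration map. It does not touch images:
object tracking, spot detection and co-registration are upstream of the
package, which consumes their CSV exports. Frames are 0-indexed everywhere;
untracked frames are encoded as empty CSV cells (zero is a legal intensity);
the default frame interval is 8 s (0.125 Hz), so a 900-frame recording spans
2 h.

## Track filtering and detrending

A cell enters the analysis only if it was tracked for at least 600
contiguous frames (45 min at 0.125 Hz). The kept trace is truncated to its
longest contiguous run (earliest on ties) rather than gap-interpolated:
interpolation would fabricate dynamics that the entropy and Hurst metrics
are specifically sensitive to. Whether to truncate before or after
detrending is a genuinely open ordering question; the package truncates
first so the baseline is fit only to frames that are actually analyzed.

Slow multiplicative drift is removed with the Eilers–Boelen asymmetric
least-squares baseline: minimize Σ wᵢ(yᵢ − bᵢ)² + λ Σ(Δ²bᵢ)² with
wᵢ = p above the baseline and 1 − p below, iterated to weight convergence
(at most `max_iter` passes; a non-converged fit returns the last iterate
with a flag, never an exception). Defaults λ = 1e5, p = 0.01, 10 iterations:
at 8-s frames this baseline tracks drifts on the many-minute scale while
passing over multi-frame spikes, and p ≤ 0.05 keeps positive transients out
of the baseline (verified by a spike-count-invariance test against ramp
injection). The correction is additive and mean-preserving — the
mean-centered baseline is subtracted, y − (b − mean(b)) — so corrected
traces keep the raw window's mean exactly and "percent of baseline" spike
thresholds stay interpretable in the original intensity units. A
ratiometric y/b mode was considered and rejected: it rescales spike
amplitudes nonuniformly across the recording, which would make the fixed
amplitude-threshold ladder mean different things at different times.

## Spike counting

Baseline B is the mean of all time points of the (detrended) trace,
recomputed per cell. A spike at threshold m is a maximal run of at least two
consecutive frames with value ≥ m·B; runs separated by one or more
sub-threshold frames are distinct. The six thresholds (1.25, 1.5, 2, 3, 4,
8 × B) are deliberately redundant: frequent low-amplitude activity and
sparse high-amplitude activity separate populations at opposite ends of the
ladder. Rates are reported in spikes per hour, derived from the frame
interval. Note that *run counts* need not be monotone in the threshold
(adjacent runs can merge at low thresholds); the monotone invariant, which
the tests assert, is the count of supra-threshold *frames*.

## Average power

P = (1/T) Σ Xᵢ². The package computes this on the mean-normalized
fluctuation Xᵢ = vᵢ/mean(v) − 1 by default: with raw intensities the sum is
dominated by the DC offset (squared mean), which varies with dye loading and
illumination and says nothing about dynamics. A raw-units mode
(`power_mode="raw"`) is kept behind a flag; the mode used is part of the
report metadata.

## Hurst exponent (rescaled range)

Dyadic window lengths L = 8, 16, 32, … ≤ T/2; the series is cut into
⌊T/L⌋ non-overlapping windows; per window the cumulative deviation from the
window mean is formed, R is its range and S the sample (n−1) standard
deviation; windows with S = 0 are excluded; the mean R/S per L is regressed
(OLS) on log₂ L.

The raw log–log slope of this procedure is substantially biased upward at
recording length ~900: E[R/S] reaches its asymptotic √L scaling slowly, and
on white noise the raw slope measures ≈ 0.58 rather than 0.5 (we checked
ddof, overlapping variants, window-mean versus global-mean subtraction, and
window ranges; none falls below ≈ 0.54). The estimator therefore subtracts
the Anis–Lloyd expected log₂ R/S of an i.i.d. series at each L (with the
Peters finite-sample factor) and reports H = ½ + slope of the excess. So
calibrated, the estimator gives 0.50 ± 0.04 on 900-frame white noise,
≈ 0.49 on shuffled spike traces, and recovers fractional-Gaussian-noise
ground truth H ∈ {0.3, 0.5, 0.8} within ±0.1 (mean over 50 seeds); the
H = 0.8 case carries the largest residual bias (≈ −0.09), a known finite-n
property of R/S on strongly persistent series. A constant trace has no
defined H (S = 0 in every window) and is reported as missing with reason,
not as a number.

## Markovian entropy

Values are discretized into n = 4 empirical quantile states; the nᵏ × n
transition-count matrix over k = 1 step histories is accumulated; row
entropies −Σ Pᵢ log₂ Pᵢ (0·log 0 ≡ 0) are summed and normalized by
nᵏ log₂ n, bounding the result in [0, 1]. Rows never visited contribute 0 —
unvisited histories carry no evidence, and including them under a uniform
prior would make the ~1.0 ceiling unreachable for finite data. Duplicate
quantile edges (low-variance traces) collapse bins while the normalization
keeps the nominal nᵏ log₂ n, so degenerate traces score predictably near 0;
a constant trace scores exactly 0. For ~900-frame i.i.d. data the estimate
sits near 0.996 rather than 1.0 because each row's plug-in entropy is biased
low by (n−1)/(2N ln 2) at ~225 transitions per state — the value the shuffle
control reproduces.

## FISH score and joining

Per plate, F₀ is the mean of the five smallest mean intensities (ties broken
by ROI ID for determinism); every cell, including the dim five, gets score
F/F₀ and positivity calls at 2×, 3×, 4×. The five-dimmest rule is applied
per plate, never across plates, since background scales with staining batch.
Metrics and FISH records are joined through the one-to-one ROI map;
unmatched cells on either side are counted and reported, never silently
dropped.

## Comparison designs and the joint significance rule

Three designs: (1) continuous association of each metric with the FISH
score — Pearson r alongside a nonlinear R² = 1 − RSS/TSS from a univariate
penalized B-spline smooth whose penalty weight is chosen by generalized
cross-validation (statsmodels basis and penalty; an explicit ridge-path GCV
solve is used for robustness to perfect fits); (2) marker-positive versus
marker-negative cells within one experiment; (3) marker-A-positive versus
marker-B-positive cells across two experiments. Group comparisons use the
asymptotic two-sample Kolmogorov–Smirnov test (samples are typically
hundreds of cells; below n = 20 the result is flagged), Bonferroni-corrected
within the family of all tests launched in one design invocation (the
family size is recorded in every result row for audit), and gated on
|Cohen's d| > 0.2 with pooled-SD d. Groups with fewer than five cells are
reported as underpowered rather than skipped. Stage-wise expression
fractions are compared with the Kruskal–Wallis rank test (p = 1 by
convention when every observation is identical).

## Randomization controls

*Shuffle control*: each trace is resampled to its own length, by default
with replacement (`randsample` semantics; a permutation mode exists — both
destroy sequential order and the control levels are insensitive to the
choice). On shuffled data the Hurst estimate falls to ≈ 0.49 and the
Markovian entropy rises to ≈ 0.996 ± 0.002 across cells, the signature that
both metrics are genuinely reading sequential structure. *Label
randomization*: cells from two marker experiments are pooled, sorted by FISH
score, and split in half; on exchangeable populations no metric reaches
joint significance.

## Synthetic data

The generator emulates the acquisition (900 frames at 8 s) and the
phenomenology the pipeline must survive: linear or exponential drift
(default 20% of baseline over the recording — within the regime the AsLS
defaults remove, as the detrend tests verify), fractional Gaussian noise of
chosen Hurst index via exact Davies–Harte circulant embedding (spectral
synthesis fallback if the embedding is not PSD), and rectangular spike
plateaus (≥ 2 frames, Poisson onsets, amplitude uniform within a
×-baseline range). Rectangular pulses rather than indicator kinetics are
deliberate: the spike definition is threshold-and-duration based, so
rectangular truth makes count recovery exact and the recovery experiment
meaningful. Noise SD defaults to 5% of baseline — enough to exercise the
quantile binning without drowning 25%-of-baseline spikes. FISH intensities
are log-normal (strictly positive, right-skewed, like real intensity data)
with a dim background subpopulation of ≥ 5 cells per plate anchoring F₀.

Two presets define the standard study conditions used by the tests and the
calibration script: a *progenitor-like* population (20 spikes/h at 1.3–1.8×
baseline, 2–4 frames, H = 0.5 noise) and a *differentiated-like* population
(5 spikes/h at 3.5–6× baseline, 3–8 frames, H = 0.8 noise). These were
chosen once as a caricature of frequent-small versus sparse-large activity
and are not tuned per test.

What the generator does *not* emulate: realistic indicator kinetics by default (a
decay-shaped pulse mode, `spike_shape="decay"`, exists for realism checks),
cell movement and segmentation error, multi-cell calcium
waves, photon shot noise statistics, and plate-level batch structure beyond
a single background level. Passing tests therefore demonstrate the
correctness and calibration of the *analysis*, not instrument-level realism.

## Problem sizes and numerical choices

The test suite and the calibration script use 50-trace control sets,
2,000–10,000-trace entropy sweeps, 2,000-replicate null calibrations, and
populations of 30–60 cells per group — sizes at which every stochastic
assertion is stable across seeds (the controls' across-seed spread is ~0.005
for entropy and ~0.04 for Hurst means). All randomness flows from explicit
integer seeds through `numpy.random.SeedSequence`; per-cell streams are
spawned from (population seed, cell index), so datasets are reproducible
element-wise, and pipeline reruns with the same config and seed are
byte-identical.

## Known limitations

* The R/S estimator's residual bias grows toward the ends of the H range;
  estimates beyond ~[0.15, 0.85] saturate at 900 frames.
* The asymptotic K-S p-value is anti-conservative below ~20 cells per group;
  such comparisons are flagged, not blocked.
* The Bonferroni family is defined per design invocation; analysts combining
  multiple invocations must account for the larger family themselves.
* The AsLS defaults assume drift slower than ~10 min; faster artifacts
  (focus jumps) are not separated from signal.
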