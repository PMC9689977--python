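# Methods

This note documents the models, parameter defaults and numerical choices
behind `glottiswt`, and what the synthetic-cohort experiments do and do
not demonstrate.

## Voice simulator

**Source model.** Each glottal cycle is a Liljencrants–Fant (LF) flow
*derivative* pulse: an exponentially growing half-sinusoid through the
main excitation at `Te = oq·T0`, followed by an exponential return phase
with time constant `Ta = ta_frac·T0`. Folding the lip-radiation
differentiator into the source this way is the standard source-filter
simplification, so rendered speech is simply the tract-filtered pulse
train. Per pulse, the return-phase rate solves
`ε·Ta = 1 − exp(−ε·(T0−Te))` (Brent), and the opening-phase growth
factor is root-found so the pulse's net area vanishes — the flow returns
to baseline within 1 % of its peak every period. The pulse is then
rescaled so its minimum is exactly `−ee`. Defaults: `oq = 0.6`,
`am = 0.78`, `ta_frac = 0.028`, values typical of modal phonation.

**Timing.** Cycle onsets live on an 8× oversampled grid (176.4 kHz) and
the train is decimated polyphase back to 22.05 kHz. At the output rate,
integer-sample pulse placement would add ~0.5-sample timing noise —
comparable to a healthy voice's jitter — so oversampling is what keeps
the "healthy" class actually healthy. Period sample counts round
half-up; the fractional residue carries to the next cycle, making the
long-run mean F0 exact.

**Perturbations.** Per cycle, the period and pulse amplitude are drawn
with relative standard deviations `jitter_pct/100` and
`shimmer_pct/100` (Gaussian); a slow sinusoidal F0 tremor is optional.
Aspiration noise is white Gaussian injected at the source; because
source and noise pass the same tract filter, the noise variance is
calibrated against the *rendered* signal power so the output reaches
the target HNR — verified by a comb-filter harmonic/noise split to
within ±2 dB on 5 s integer-period signals.

**Archetypes.** Classes differ only through perturbation magnitudes:
healthy 0.3 % jitter / 2 % shimmer / 30 dB HNR; cyst-like 1.5/10/15;
paralysis-like 2.5/15/12 plus 5 Hz tremor at 8 % depth; polyp-like
4/25/8 — spanning the range reported for real dysphonic voices. Within
a cohort, F0 is drawn uniformly from 100–220 Hz (mixed adult voices)
and the /a/ formant pattern is scaled ±10 % per speaker. Default
duration is 2 s, the midpoint of typical clinical sustained-vowel
recordings (1–5 s). All draws derive from `SeedSequence(seed)` children,
so cohorts are pure functions of `(spec, seed)`.

**What the simulator does not emulate:** diplophonia, voice breaks,
subharmonic regimes, soft phonation onset/offset, room acoustics,
channel/equipment coloration, or pathology-specific biomechanics. Its
classes are clean perturbation grades; real corpora are far messier and
also carry recording-condition confounds.

## Glottal inverse filtering

Classic two-phase IAIF, frame-wise (50 ms frames, 25 ms hop, Hamming
windows for the model fits, raw samples filtered), after a 60 Hz
zero-phase high-pass that stabilizes the integrators:

1. order-1 fit → inverse filter (spectral-tilt pre-emphasis),
2. order-`p_vt` fit → inverse filter the original frame,
3. leaky integration (first glottal estimate),
4. order-`p_gl` fit on that estimate → cancel, integrate,
5. order-`p_vt` refit → final inverse filter = flow derivative,
6. leaky integration → glottal flow.

Defaults: `p_vt = 2 + fs/1000` rounded to even (24 at 22.05 kHz),
`p_gl = 4`, integrator leak `rho = 0.99` — the canonical IAIF settings.
Frames are re-joined by Hamming-weighted overlap-add normalized by the
accumulated window. Silent frames are skipped.

**All-pole fits.** `method="lpc"` is autocorrelation linear prediction
(Levinson via Toeplitz solve, tiny diagonal load). `method="dap"`
(default) minimizes the Itakura–Saito distance between the frame's
discrete power spectrum and the all-pole spectrum: a damped fixed-point
iteration on the stationarity equations, initialized at LPC, stopped at
relative distortion change < 1e-6 or 50 iterations, tracking the best
iterate. Every returned model is stabilized by reflecting outside poles
to `1/|r|`. On the dense FFT grid used here the discrete IS optimum
coincides with LPC to ~1e-8 in the coefficients — the methods differ
materially only on sparse discrete spectra (e.g. harmonic-locked
frequency sets), which would require pitch tracking and is out of scope.

Recovery quality on clean synthetic vowels: Pearson r ≈ 0.9 between
estimated and true flow derivative over the central 80 %, degrading
monotonically as HNR drops.

## Stationary wavelet transform

À-trous scheme with circular (periodic) boundary handling. The analysis
convention is fixed as anti-causal correlation,
`y[n] = Σ_k f[k]·x[(n+k) mod L]`, with base filters upsampled by
`2^(j−1)` at level j; any consistent convention is valid, this one is
pinned so coefficient-level results are reproducible. The lowpass is
the orthonormal scaling filter (from PyWavelets, natural order), the
highpass its alternating-sign reversal; the pair satisfies
`|L(ω)|² + |H(ω)|² = 2`, which makes the synthesis
`A_{j−1} = (conv(lo_j, A_j) + conv(hi_j, D_j))/2` exact to ~1e-13.
Inputs whose length is not a multiple of `2^J` are edge-replicated up
to it and the stored bands truncated back. Filtering runs in the
Fourier domain (folded filters), so a 5-level decomposition of a 2 s
recording costs a handful of FFTs. Default `J = 4`, Haar.

## Descriptors

Per band: energy, power entropy, mean, variance (L−1 denominator),
standard deviation, kurtosis `m₄/σ⁴`, skewness `m₃/σ³`, where the
central moments use `1/L` and σ is the (L−1) value — the convention is
pinned because mixed-denominator variants differ at small L. The
entropy is Shannon entropy (base 2) of the normalized *squared*
coefficients: a literal `−Σ W log W` is undefined for the signed
coefficients a wavelet transform produces, so the relative sub-band
energy distribution ("power entropy") is used; a magnitude-based
literal variant remains available behind `entropy_mode="literal"`.
Constant bands (σ = 0) yield kurtosis = skewness = 0 rather than
errors. The recovered flow is normalized to unit variance before
decomposition: the inverse-filter gain is arbitrary, so absolute flow
scale is an artifact, and without this step the scale-dependent
descriptors mostly measure tract gain.

## Selection and classification

Information gain uses equal-width discretization over `[min, max]`
with 10 bins (quantile binning available), base-2 logs, ties in the
ranking broken by feature name. IG is clamped to `[0, H(labels)]`.

The linear SVM is trained by per-sample SGD on
`λ‖v‖²/2 + max(0, 1 − t(v·s − k))` with `η_t = η₀/(1 + η₀λt)`,
`η₀ = 0.1`, `λ = 1e-4`, 100 epochs, per-epoch reshuffling from the run
seed, bias unregularized, one-vs-rest for multiclass. The RBF-kernel
SVM delegates to libsvm (`sklearn.svm.SVC`, C = 1,
`gamma = 1/(d·var)`). Cross-validation is stratified k-fold (per-class
round-robin after a seeded shuffle, counts differing by ≤ 1); the
min/max scaler and, when used, the IG ranking are refit inside each
training split, so no test information leaks into scaling or
selection. Metrics are micro-pooled over folds: CA, support-weighted
PPV/recall/F1, and AUC as the Mann–Whitney rank statistic (macro
one-vs-rest for multiclass).

## Experiment harness

`run_experiment` materializes cohorts from `(config, seed)` and runs
detection, multiclass, cross-cohort transfer (training cohort's scaler
always applied to the foreign test set, consistent with the
train-derived scaling rule), and level/wavelet sweeps. Reports are
JSON plus flattened CSV and embed provenance (config hash, seed,
wavelet, level, IAIF method). Re-running a config reproduces its
report bit-identically.

## Known limitations

- **Signed detail means are degenerate.** The highpass taps sum to
  zero, so under any periodized SWT the sum — hence the mean — of every
  detail band is exactly zero up to boundary-truncation leakage. The
  `Mean-D*` descriptors therefore carry only weak edge effects
  (|values| ~1e-4 after unit-variance scaling) and rank mid-table by
  IG on synthetic cohorts. Reports of detail-band means as top
  discriminators are only explicable with non-periodic boundaries or
  magnitude statistics; this implementation keeps the signed formula
  and documents the consequence rather than silently switching.
- **Haar leakage bounds band selectivity.** Haar filters roll off so
  slowly that the D1–D3 bands of the integrated flow are dominated by
  leakage from the first-formant region, ~30 dB above the in-band
  aspiration-noise cue; band statistics therefore barely see HNR
  differences, and the discriminative channel on synthetic cohorts is
  flow-shape statistics (Pentropy/Kurtosis/Skewness of A-bands).
  Higher-order Daubechies wavelets (the `sweep_wavelets` mode) trade
  this leakage against time resolution.
- On the default 60 + 60 strongly perturbed cohort, the hand-rolled
  SGD linear SVM with all 56 features reaches ~94–96 % pooled CA
  (AUC ≈ 0.97); three-feature subsets cap near 70–78 % for any
  classifier because of speaker (F0/tract) nuisance variability that
  the three features cannot absorb. Passing synthetic tests bounds
  implementation correctness, not clinical performance: no claim about
  real pathological voices follows from these cohorts.
- Problem sizes in the test suite and acceptance script (cohorts of
  20–120 two-second recordings, 100-signal transform sweeps) are chosen
  to make the full chain cheap to re-run; all scale linearly if larger
  studies are needed.
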