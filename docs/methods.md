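# Methods

## Problem and model

Cerebral autoregulation (CA) keeps cerebral blood flow roughly constant
across changes in perfusion pressure. A robust noninvasive index of CA is
the phase shift (PS) between spontaneous Mayer-wave oscillations
(0.05–0.15 Hz, centered near 0.1 Hz) of arterial blood pressure (BP) and of
blood flow velocity (BFV) in the middle cerebral artery: with intact
autoregulation BFV leads BP by roughly 1 rad; the lead shrinks under
hypercapnia (CO₂ inhalation, toward ~0.45 rad) and grows under hypocapnia
(hyperventilation, toward ~1.4 rad).

Both channels are modeled as locally stationary mixtures of oscillatory
components — cardiac (~1 Hz), respiratory (~0.25 Hz), Mayer (~0.1 Hz),
B-waves (~0.02 Hz) — plus broadband noise. The package estimates, in
sliding frames, (i) whether BP and BFV oscillate coherently in the Mayer
band, (ii) at which frequency, and (iii) with what phase. Two back-ends
implement the same contract.

Sign convention everywhere: the cross spectrum is `S_xy = conj(X)·Y` with
`x` = BP and `y` = BFV, so a positive phase means BFV leads BP.

## Welch (STFT) back-end

Frames of `N_frame = 16384` samples at `dt = 0.01 s` (163.84 s) advance by
`N_shift = 512` samples (5.12 s). Inside a frame, windows of
`N_win = 2048` samples (20.48 s) slide with the same 512-sample stride;
only windows fully inside the frame are used (29 with defaults). Per
window both channels are mean-centered, Hamming-tapered and transformed;
auto and cross spectra `|X|²/N_win`, `|Y|²/N_win`, `conj(X)Y/N_win` are
averaged over the windows. The squared coherence

    C(k) = |S_xy(k)|² / (S_xx(k) · S_yy(k))

is maximized over the DFT bins inside 0.05–0.15 Hz (bin spacing
1/20.48 s ≈ 0.0488 Hz leaves bins at 0.0977 and 0.1465 Hz; ties break to
the lower frequency). If `C(k_M) ≥ 0.6` the frame emits
`arg S_xy(k_M)`; otherwise a gated (phase-free) sample keeps the
timestamp, so downstream gap statistics remain computable. Bins with zero
averaged power get coherence 0, never NaN. Note that the frame/offset
quotient 16384/512 equals 32; the number of windows *fully inside* a
frame is 29 — both counts are reported by the validation code.

No linear detrending is applied (centering only), and no confidence
intervals are attached. Coherence and phase are ratio/argument quantities,
so one-sided scaling constants cancel; this is asserted by an
amplitude-invariance property test.

## Wavelet (CWT) back-end

The analytic Morlet wavelet with center frequency `ω₀ = 6` is applied in
the Fourier domain: each frame (mean-centered, zero-padded to the next
power of two strictly above its length to suppress circular wrap) is
multiplied per scale by

    ψ̂(s·ω) = π^(−1/4) · exp(−(s·ω − ω₀)²/2) · H(ω) · (2π·s/dt)^(1/2)

where the Heaviside factor `H(ω)` zeroes non-positive frequencies, making
the coefficients analytic (instantaneous phase is well defined). Scales
form a dyadic grid `s_j = s₀·2^(j·δj)` with `s₀ = 2·dt`, `δj = 1/12`
(12 voices per octave) and `J = δj⁻¹·log₂(N·dt/s₀)`; each scale maps to
the pseudo-frequency `f = ω₀/(2π·s)`. This mapping is the package's
definition throughout; it differs from the Torrence–Compo Fourier-wavelength
factor by about 3% at `ω₀ = 6`. With it the 0.05–0.15 Hz band covers
about 19 grid frequencies.

Cross spectrum `conj(c_x)·c_y` and the two powers are smoothed before the
coherence ratio is formed — without smoothing the ratio is identically 1.
Time axis: Gaussian kernel with σ equal to one scale unit (`σ = s/dt`
samples; configurable factor, default 1), truncated at 4σ, renormalized at
the record edges so constants are preserved. Scale axis: centered moving
average over 12 scale bins (one octave), shrunk at the grid edges. A
cone of influence (COI) excludes cells closer than `√2·s` (the e-folding
distance of the Morlet envelope) to a frame edge from all aggregation.

Per frame, the Mayer scale is the band scale with maximal mean squared
coherence over admissible cells ("max" criterion; the alternative
"fraction" criterion maximizes the share of suprathreshold cells and
breaks its frequent saturation ties by mean coherence — on stationary
coherent input both pick the same scale). The frame gate compares the
*mean* squared coherence at that scale, taken over the frame's
COI-admissible cells, against the 0.6 threshold: gating on "any
suprathreshold cell" would fire on isolated noise excursions, and a mean
over only a few cells has too much variance to reject noise reliably. An
ungated frame emits the circular mean of the phases of suprathreshold
cells.

The time axis is collapsed over the frame's **central stripe** (25% of the
frame, ~41 s with defaults, intersected with the COI). Averaging the whole
163.84-s frame instead would discard exactly the temporal resolution that
distinguishes the wavelet estimator from the Welch estimator: with
full-frame averaging the two back-ends localize phase transitions equally
(their errors become noise-dominated and statistically indistinguishable),
whereas the stripe keeps the wavelet estimate at its native resolution
(stripe width plus smoothing support, roughly 100 s against 164 s) and
measurably sharpens transition localization. Degenerate short frames fall
back to the full COI mask, then to all cells.

## Streaming

A ring buffer keeps the newest frame per channel; every `N_shift` new
samples the configured back-end runs on the buffer. Warm-up delay is one
frame (163.84 s); each emission depends only on samples up to its frame
end. Batch and streaming paths share the identical per-frame code, so
replaying a file through the engine reproduces the batch series
bit for bit at any chunk size. Emission timestamps default to the frame
end ("PS as of now, computed over the trailing 163.84 s"); a frame-center
convention is available and is used by the validation experiments where
estimates are compared against ground truth at the time they describe.
Frames are recomputed in full at every update; no incremental spectral
updates are attempted (correctness over speed).

## Synthetic hemodynamics

The simulator emulates the component structure above with defaults:
BP = 90 mmHg baseline with amplitudes (5, 3, 2, 1) mmHg and BFV = 60 cm/s
baseline with (10, 5, 4, 2) cm/s for cardiac 1.1 Hz, respiratory 0.25 Hz,
Mayer 0.10 Hz and B-wave 0.02 Hz, all components in phase between channels
except the Mayer component of BFV, whose instantaneous argument is advanced
by the prescribed θ(t). θ profiles are piecewise plateaus with linear
ramps; because θ enters the phase argument directly, the signals stay
phase-continuous across events. White Gaussian noise is drawn
independently per channel from a generator seeded by the spec; output is a
pure function of the spec.

Noise defaults (σ_BP = 9 mmHg, σ_BFV = 18 cm/s) were derived analytically
so that the squared coherence at the Mayer bin is ≈ 0.9 under the default
Welch geometry: the per-bin SNR of a tapered sinusoid is
`ρ = A²(Σw)²/(4σ²Σw²)`, and `γ² = 1/((1+1/ρ_x)(1+1/ρ_y)) = 0.9` gives
`ρ ≈ 18.5` per channel. This places typical operation above the 0.6 gate
while leaving the gate active, so both branches are exercised.

The simulator is phenomenological: θ is imposed, not produced by a
feedback (Windkessel-type) model. Real recordings add nonstationary
amplitudes, inter-component coupling, measurement artifacts and
non-Gaussian noise; passing tests therefore demonstrate correctness of the
estimators under the stated signal model, not clinical performance.

## Reactivity metrics

Phase statistics are circular (resultant-vector means), immune to wrap
artifacts near ±π. Reactivity to a standardized load is
`η = (θ_ext − θ̄)/θ̄` with `θ̄` the circular mean of ungated baseline
phases and `θ_ext` the extremum of the 3-sample-median-smoothed ungated
phases in the test interval (min for hypercapnia, max for hypocapnia);
the smoothing prevents single-sample spikes from defining the extremum.
`coherent_fraction` is the share of ungated samples. The recovery report
computes bias and RMSE of ungated samples against a truth profile on its
plateaus, and a transition-localization error: the estimated step time is
the least-squares fit of a two-level step (levels taken from the truth)
over all candidate boundaries — far more robust to phase noise than a
first-crossing rule, and applied identically to both back-ends.

## Validation experiment sizes

The validation module synthesizes every input it measures. Plateau
recovery uses constant-θ records of 700 s (comparable to one condition
phase of a capnia protocol) at the anchor levels 0.45/0.98/1.37 rad,
20 seeds per level; because consecutive default-advance frames share 97%
of their samples, the wavelet back-end emits there on a thinned 40.96-s
advance (each frame computed exactly as in the default pipeline; the
stripes then tile the record). Step localization uses 420-s records with
a 0.98→1.37 rad step and both back-ends on identical recordings with
frame-center timestamps. Gating specificity uses 50 single-frame records
of channel-independent noise. Batch/stream agreement replays one 220-s
recording at chunk sizes 1, 100 and 4096.

## Known limitations

- No significance testing of wavelet coherence against red-noise
  surrogates, and no bias-rectified scalograms.
- The coherence gate threshold (0.6, recommended range 0.5–0.75) is an
  empirical setting, not a computed significance level.
- Group statistics across subjects are out of scope.
- The EDF device format is not read; recordings travel as CSV.
- Hardware acquisition, clock drift and transport are out of scope.
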