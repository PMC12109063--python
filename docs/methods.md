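# Methods

## Signal model and assumptions

The pipeline assumes a single-channel sEMG recording of repeated
contraction cycles under constant load, sampled uniformly (2 kHz nominal).
The fatigue-relevant physiology is summarized by one statistic: the median
frequency (MF) of the power spectral density of the signal's
high-frequency component, which declines approximately linearly with time
as the muscle fatigues. Everything downstream of the decomposition treats
the MF trajectory as `y = A·x + b` plus noise; sessions whose MF does not
drift (light load, no fatigue) produce a near-zero slope and are handled
by the estimator's clamping rather than by a separate code path.

## Conditioning

Band-pass 10–400 Hz, 4th-order Butterworth, plus a second-order IIR notch
at 50 Hz with quality factor Q = 30, both applied forward–backward
(zero-phase) with odd-symmetric padding. Zero-phase filtering matters
because window-center times enter the drift regression; group delay would
bias the intercept. The filter family and order are conventional sEMG
conditioning choices; both band edges, the notch frequency and Q are
configurable (`band_low`, `band_high`, `notch_hz`, `notch_q`).

## EMD / EEMD

EMD sifts the signal into intrinsic mode functions by repeatedly
subtracting the mean of the upper/lower extrema envelopes:

* Envelopes are natural cubic splines through the local extrema, with two
  extrema mirrored past each boundary to suppress end swings.
* A sift is accepted when the Cauchy-style criterion
  SD = Σ(h_prev − h)²/Σh_prev² < 0.2 holds together with the IMF condition
  |#extrema − #zero-crossings| ≤ 1, or after 50 sifts.
* Decomposition stops when the residue is monotone/has fewer than three
  extrema or `max_imfs` (default 8) is reached. Each IMF is literally
  subtracted from the running residue, so IMFs + residue reconstruct the
  input to float round-off by construction.

EEMD decomposes `ensemble_size` white-noise-perturbed copies
(`noise_ratio` × signal SD, default 0.2) and averages IMFs component-wise;
realizations with fewer IMFs are zero-padded in component index. Noise for
realization *m* comes from substream *m* of the master seed
(`SeedSequence(seed, spawn_key=(m,))`), so growing the ensemble never
reshuffles earlier realizations and results are reproducible bit-for-bit.
With `ensemble_size=1, noise_ratio=0` EEMD degenerates exactly to EMD.
The ensemble mean reconstructs the input up to the mean of the added
noise, which shrinks as 1/√M.

Only IMF1 (the highest-frequency component) feeds the fatigue analysis;
when only it is needed, `max_imfs` can be lowered (sifting is sequential,
so IMF1 is unchanged) to cut runtime roughly in proportion.

## Median-frequency tracking

Windows are 10,240 ms stepped by 2,560 ms — long enough for ~0.1 Hz
spectral resolution, short enough to track the drift; trailing samples
that do not fill a window are dropped rather than padded, because padding
would bias the terminal MF that anchors the calibrated range. Each window
gets a single Hann-tapered, mean-detrended periodogram (Welch
sub-averaging is available via `welch_nperseg` but off by default). MF is
the half-energy point of the cumulative trapezoid integral of the PSD,
located by linear interpolation between grid points — so a flat spectrum
on [0, 100] Hz gives exactly 50 Hz and MF is not quantized to the bin
width. A zero-power window raises a degenerate-spectrum error rather than
returning an arbitrary value.

## Drift fit, calibration, estimator

Per session, MF is regressed on window-center time by ordinary least
squares. R is reported as the |Pearson correlation|: fatigue slopes are
negative and only the magnitude of the association is meaningful. mf_S is
the fitted line evaluated at the last window center (not the last raw MF
sample), which is robust to single-window noise. A zero-variance MF series
yields slope 0 with a `degenerate` flag instead of an error.

Calibration averages training-session intercepts and terminal values into
[MF̄₀, MF̄ₛ], independently per subject and load — fatigue responses do
not transfer across subjects. If MF̄₀ ≤ MF̄ₛ the model is flagged as
carrying no fatigue range and the estimator refuses it.

The quantizer tiles the range with N half-open intervals
(MF̄₀ − (2k+1)Δ/2, MF̄₀ − (2k−1)Δ/2], Δ = (MF̄₀ − MF̄ₛ)/(N − 1), k = 0…N−1,
and reports LF = k/(N − 1). Design choices:

* **Out-of-range orientation.** The estimator clamps values *above* the
  range to k = 0 (no fatigue) and *below* it to k = N − 1 (full fatigue) —
  the orientation consistent with MF falling as fatigue rises. The
  opposite orientation (below → no fatigue, above → full) appears in some
  formulations but contradicts the physiology; a `printed_clamp` flag
  reproduces it for audit.
* **Ties.** A value exactly on an interval edge joins the lower-frequency
  (more fatigued) interval — deterministic and monotone.
* **N.** N = 3 is the default (best accuracy/stability trade-off among
  N ∈ {2, 3, 4}); N is configurable and the interval formula holds for any
  N ≥ 2.

## Synthetic generator

`synth.generate` emulates the statistical structure of cyclical-fatigue
sEMG, not its physiology: Gaussian noise is band-pass shaped (0.5 s
blocks, 50%-overlap Hann crossfade, 4th-order Butterworth of configurable
bandwidth, default 40 Hz) around a center that drifts linearly from
`mf_start` to `mf_end`; a raised-cosine contraction envelope with a 25%
rest fraction per 4 s cycle modulates the amplitude
(1 + mod_depth·burst(t)); optional 50 Hz interference and a broadband
noise floor (relative power 0.02) are added. The "true MF" of the
symmetric band is taken to be its center; filter-rolloff asymmetry is
small relative to the ±5 Hz tolerances used in validation. Defaults
(136 → 122 Hz over 160 s at 2 kHz) reproduce a heavy-load session; setting
`mf_start == mf_end` gives the light-load, no-fatigue control.

What the generator does **not** emulate: motor-unit recruitment and firing
statistics, amplitude growth with fatigue (RMS/iEMG trends), motion
artifacts, electrode noise spectra, or inter-cycle kinematic variability.
Passing tests therefore demonstrate that the pipeline recovers a known
spectral drift under realistic noise — not that it handles every artifact
of clinical recordings.

## Numerical choices and degenerate inputs

* Zero-phase filtering uses odd padding of 3× the (doubled) filter order;
  traces shorter than the warm-up are rejected.
* EMD plateaus (zero slope) inherit the previous slope sign when locating
  extrema; monotone inputs return zero IMFs with residue = input.
* The MF interpolation is linear on the cumulative energy within the
  straddling bin; the independent test oracle implements the same
  convention with separate code.
* Constant windows, empty training sets, inverted calibration ranges and
  non-finite inputs raise typed errors (`DegenerateSpectrumError`,
  `InsufficientDataError`, `NoFatigueRangeError`, `InputError`) rather
  than propagating NaNs.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` generate sessions at the full
study scale (160 s at 2 kHz, 59 analysis windows). Drift-parameter
recovery uses 20 independent seeds on the raw generator output.
End-to-end staging (3 training + 2 held-out sessions + 1 drift-free
control) runs EEMD with ensemble_size = 4, noise_ratio = 0.1 and
max_imfs = 2: the staging result depends on the ensemble mean of IMF1,
which is already stable at small ensembles for these band-limited signals,
and larger ensembles only polish higher-order IMFs the estimator never
reads. Unit tests exercise the ensemble-size convergence property
separately on short signals (ensemble 10 vs 100).

## Known limitations

* EMD boundary handling (two mirrored extrema) can still distort the first
  and last fraction of a second; the 10 s analysis windows make this
  negligible for MF, but per-cycle analyses would need better boundaries.
* The linear MF model is a deliberate simplification; strongly nonlinear
  fatigue trajectories (e.g., late-session collapse) are flattened into
  the line before staging.
* Calibration requires at least one fatiguing training session; the
  estimator cannot invent a range for a subject who never fatigued.
* No CEEMDAN or other EEMD variants; no multi-channel fusion; no
  real-time/streaming operation.
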