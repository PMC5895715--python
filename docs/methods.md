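# Methods

This note documents the models implemented in `ffsmvep`, the parameter
choices that matter, and the limits of what the synthetic data can show.

## Stimulus model

The stimulus is an annulus (outer diameter 100 px, inner 20 px by default)
of `n_rings = 8` concentric rings of equal radial width, each divided into
`n_sectors = 16` equal angular sectors. A check at ring index `i` and
sector index `j` is bright when `(i + j)` is even. Because bright and dark
checks tile the annulus in equal areas, total and local mean luminance are
invariant as the texture moves — the flicker-free property. Rendering uses
a Cartesian grid (default 200×200) with the pattern centred, radius in
pixel units and angle counter-clockwise from +x; the measured per-frame
mean-luminance relative SD at full contrast is ~1e-4, well below the 1 %
contract asserted in tests.

Radial motion follows the raised cosine

    s(t) = (A/2) · (1 − cos(2π f_cyc t)),   f_cyc = f_rev / 2,

which starts from rest, reaches the amplitude extremum `A` mid-cycle, and
reverses direction twice per cycle — so the motion-reversal rate `f_rev`
is the evoked-response fundamental and `f_cyc` its first subharmonic. `A`
defaults to 10 px, the midpoint of the 5–15 px range the paradigm uses.
Ring indices are computed modulo the annulus width, so rings leaving the
annulus reappear at the opposite edge ("a new ring appears"); with an even
ring count the pattern is exactly periodic in displacement with period
`2 × ring_width`.

A display holds each frame for one refresh interval; `sampled_motion_signal`
models this as a zero-order hold evaluated on a dense grid (7200 Hz
default, i.e. 50× the 144 Hz refresh, chosen so hold steps of both 60 and
144 Hz displays land on grid points). Discretization error is summarized
two ways: RMS deviation from the continuous trajectory, and the largest
amplitude-spectrum peak away from the motion frequency (hold images at
`k·f_refresh ± f_cyc`). Both shrink monotonically with refresh rate.

## Synthetic EEG

Each trial is a samples × channels matrix at `fs = 1200` Hz over six
occipital/parieto-occipital channels (Oz, O1, O2, PO1, POz, PO2) with
response gains (1.0, 0.8, 0.8, 0.7, 0.9, 0.7) — Oz strongest. The evoked
response for stimulation frequency `f` is

    gain_c · m(contrast) · Σ_h a_h sin(2π h f (t − τ) + φ_h),   t ≥ τ,

with visual latency `τ = 150` ms and phase offsets 0 by default. Harmonic
amplitude profiles (in arbitrary units; absolute scalp µV is not modelled):

- motion (SSMVEP): `a = (1.0, 0.15, 0.05)` — fundamental-dominant;
- flicker (SSVEP): `a = (1.0, 0.5, 0.25, 0.12, 0.06)` — five usable
  harmonics.

These profiles are calibration knobs; the defaults were set so the decoded
harmonic-to-fundamental canonical-correlation ratio of the motion profile
sits clearly below the flicker profile's, the qualitative signature that
motivates single-harmonic references.

The contrast multiplier is the saturating logarithm
`m(c) = log(1 + c/c0) / log(1 + 1/c0)` with `c0 = 8e-4`, solved once so
that `m(0.25) ≥ 0.8`: the response rises steeply at low Michelson contrast
and is nearly saturated past 0.25.

Background activity per channel: 1/f ("pink") noise made by 1/√f spectral
shaping of white noise (log–log PSD slope ≈ −1 over 2–40 Hz), alpha-band
activity modelled as unit-SD white noise band-passed 8–12 Hz (real alpha
waxes and wanes; a phase-coherent 10 Hz sinusoid would be an artificial
worst-case confound for a sinusoid-template decoder), common-phase 50 Hz
mains, and white noise. Default amplitudes (1.0, 0.8, 0.5, 0.5 relative to
a unit-amplitude fundamental) put 2-s decoding near ceiling and 1-s
decoding visibly below it, matching the regime in which the online speller
operates (90–99 % at 2–3.5 s stimulation). All randomness flows from
`numpy` seed sequences; per-trial seeds are spawned from the session seed.

What the generator does *not* emulate: volume-conducted channel
correlations beyond shared gain, eye-blink/EMG artifacts, inter-subject
variability, fatigue drift, or phase-locked harmonic structure of real
flicker responses. Passing tests therefore demonstrate the pipeline's
correctness and its qualitative contrasts, not human-subject performance.

## Preprocessing

Band-pass 2–100 Hz and band-stop 48–52 Hz are order-4 Butterworth filters
applied forward–backward (`sosfiltfilt`) for zero phase; the narrow 2–22 Hz
preset serves the contrast analysis. Epochs start 150 ms after stimulus
onset (visual-pathway latency). Segment averaging uses non-overlapping
segments with the trailing remainder discarded; the default segment length
is one full motion cycle (two reversal periods), exposed as a parameter.
Amplitude spectra use a Hamming window with coherent-gain correction
(2 / Σw, DC and Nyquist bins not doubled) so a unit sinusoid at a bin
centre reads ≈ 1. Spectral SNR is the amplitude at the bin nearest `f0`
divided by the mean of the 10 nearest bins on each side — a local
peak-to-background measure, defined here because the pipeline needs a
number where the paradigm's description is qualitative.

## CCA decoding

References follow `Y_i = [sin(2π f_i n); cos(2π f_i n)]` with
`n = 1/Fs … K/Fs`, optionally extended with harmonic pairs; the default is
a single pair (H = 1), which is the operating contract of the motion
paradigm. The solver centres rows, takes thin SVDs of both sample-major
matrices, and reads the canonical correlations off the singular values of
`U_xᵀ U_y` restricted to singular subspaces above `max(shape)·eps·σ₁`.
This is numerically stable and absorbs rank-deficient inputs (noise-free
channels are exact scalar multiples of each other) without ridge
regularization; only zero-variance inputs raise an error. Tests pin the
solver to an independent brute-force oracle — the explicit
`C_xx⁻¹ C_xy C_yy⁻¹ C_yx` eigenvalue solve — to 1e-8 on 200 random
instances. Classification takes `argmax ρ` over the candidate grid with
ties resolved to the first (lowest, for an ascending grid) candidate. The
coefficient-spectrum analysis evaluates ρ against single-harmonic
references on a response-frequency grid (default 0.4 Hz steps) per
stimulation frequency.

## Speller and ITR

The speller arranges 40 targets in 5 rows × 8 columns, tagged 7.0–14.8 Hz
in 0.2 Hz steps (values rounded to 0.1 mHz to keep the grid exact); the
default character set is A–Z, 0–9 and four punctuation marks. Simulated
online sessions present every target once per block in seeded random
order, synthesize each trial, and decode it with the CCA classifier.

The Wolpaw bits-per-selection bracket is continuous at `p = 1` and equals
0 exactly at chance `p = 1/N`; it is mathematically non-negative on
(0, 1] (its minimum is at chance), so the defensive zero-floor never
alters a value. Rates use `T` = stimulation time + 0.5 s gaze shift; this
convention reproduces 16 of the 18 published per-subject ITRs to ±0.01
bits/s, and the summary utility therefore reports the published ITR column
and the recomputed one separately (the two discrepant rows are consistent
only with `T` excluding the gaze shift). Column summaries use sample
standard deviations (n − 1).

## Problem sizes and determinism

The test suite and the acceptance script run full 40-class problems with
2–3 s epochs: the monotonicity sweeps use 5 trials per class at three
noise levels and three durations (600 decoded trials per sweep), the
harmonic-ratio contrast uses one 2.5 s trial per frequency per paradigm,
and the simulated online session uses 6 blocks × 40 targets at 2 s
stimulation. These sizes give stable statistics at interactive runtimes.
Every stochastic step is seeded; reruns are byte-identical.

## Known limitations

- The renderer is nearest-pixel (no anti-aliasing); sub-pixel motion below
  ~0.5 px per frame quantizes to identical frames at coarse resolutions.
- The flicker comparison is defined purely by the harmonic-rich response
  profile; no luminance-flicker stimulus is rendered.
- EDF export is not provided; delimited matrices with JSON sidecars are
  the interchange format.
- Real-subject quantities (population CCA-coefficient means, significance
  tests, fatigue ANOVA) are out of scope: the substituted checks assert
  directional/structural properties on synthetic data only.
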