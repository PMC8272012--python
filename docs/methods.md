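# Methods

`usctfwi` reproduces, at desk scale, a complete ultrasound-computed-
tomography (USCT) imaging chain for speed of sound (SoS) in breast-like
media: ring-array data simulation, learned low-frequency bandwidth
extension, frequency-stepped full-waveform inversion (FWI), and
travel-time system calibration. This note records the models, the
parameter choices that matter, the numerical decisions, and what the
desk-scale experiments do and do not demonstrate.

## The physical problem

Clinical phased-array probes transmit almost no energy below roughly a
quarter of their centre frequency; a 2 MHz cardiac array's transmission
spectrum falls 40 dB below its peak near 0.5 MHz. Frequency-stepped FWI
started from a homogeneous water model needs the observed and simulated
wavefields to agree within half a cycle at the *starting* band; for
breast-sized targets, water-vs-tissue travel-time errors of several
microseconds make 0.5 MHz far too high, and the inversion locks into a
cycle-skipped local minimum. The package's central demonstration is the
standard escape route: train a network on simulated acquisition pairs to
extrapolate the missing low band, then invert the extrapolated data with
a lower starting frequency.

## Forward model

The solver integrates the constant-density scalar wave equation
`m ∂²p/∂t² = ∇²p + s`, with `m = 1/c²` (slowness squared), using a
4th-order spatial stencil and 2nd-order leapfrog in time. Density and
attenuation are not modelled; the inversion unknown is SoS only.

* **Stability / accuracy.** The explicit scheme is stable for
  `dt ≤ 0.612·h/c_max`; solvers default to 80–85 % of that limit, and the
  suite validates ≥ 8 points per wavelength for physics oracles (first
  arrivals within 2 % of `distance/c`, reciprocity within 1 %).
* **Boundaries.** An exponential-damping sponge (Cerjan-style, default
  16–25 cells, per-step factor `exp(−(0.03·(W−k))²)`) keeps late-time
  wrap-around below 1 % of the direct-arrival peak. The sponge is part of
  the linear operator, so the adjoint treats it exactly.
* **Sources/receivers.** Off-grid positions are handled by bilinear
  injection/sampling. Receiver traces are resampled onto a coarser output
  grid (default 1 µs at desk scale) by *linear interpolation in time*
  inside the receiver operator rather than by anti-alias decimation; the
  output Nyquist is kept ≳ 2× above the wavelet band, so aliasing is
  negligible, and the operator has an exact transpose — this is what lets
  the adjoint dot-product test pass at ~1e−14 at any output rate.
* **Adjoint state.** The forward pass stores the source-side field
  `W[n] = σ(A p[n−1] + s[n−1])`; the adjoint runs the exact transpose of
  the discrete update and correlates against `W`, yielding the gradient
  with respect to slowness squared. A Born (linearized) forward provides
  the matching Jacobian action for dot-product verification.

## Wavelets

* `narrowband_wavelet`: Gaussian-enveloped tone burst; defaults
  (fc = 2 MHz, −6 dB fractional bandwidth 0.6) put the −40 dB low edge
  near 0.45 MHz, emulating a cardiac-probe transmission.
* `ideal_pulse`: 3-cycle Hann-windowed sinusoid. Its −40 dB low edge
  sits near 0.35·fc, so the full-scale default fc = 0.25 MHz gives the
  spliced hybrid a low edge below 0.1 MHz. The centre frequency is
  deliberately configurable: only the pulse's 3-cycle shape and the
  target band edge are fixed design points.
* `hybrid_broadband`: frequency-domain splice keeping the narrowband
  spectrum above the 1 MHz split and the (amplitude-matched) ideal-pulse
  spectrum below it, cosine-crossfaded over 0.1 MHz; the inverse FFT of
  the conjugate-symmetric spectrum is the broadband source used for
  target-data simulation. The hybrid's low edge is bounded below by the
  ideal ingredient's own edge.
* Band edges are measured on the zero-padded amplitude spectrum with
  log-domain linear interpolation between bins, relative to the global
  peak. All filtering (high-pass, low-pass, sliding band-pass) is
  zero-phase FIR (forward–backward), so band limiting never moves first
  arrivals — verified to within 2 samples.

## Phantoms

`make_breast_phantom` renders: water at 1484 m/s, a smooth wobbled
circular outline, a slow fat annulus, a glandular interior of
`mean + band-limited Gaussian texture` (Gaussian-filtered white noise at
a stated correlation length), circular inclusions, and sparse single-cell
scatterers, all clipped to 1300–1800 m/s. The generator is a statistical
stand-in for anatomical slice data: it reproduces the SoS range and the
layered geometry, not anatomy. Texture has no published model; the
Gaussian-field choice is the simplest stationary one.

## Desk-scale study design

Everything the tests run uses one scaled configuration (`presets.DESK`),
chosen by preserving the dimensionless skip number `N = f_min · ΔTOF`
(lowest usable frequency × water-vs-tissue travel-time error) rather
than by scaling frequencies alone:

| quantity | desk value | rationale |
|---|---|---|
| grid | 128×128 at 1.2 mm | resolves the 210 kHz stop band at ≥ 5 ppw |
| ring | 8 probes × 16 elements, 104 mm | same topology as 16 × 96 / 200 mm |
| narrowband source | fc 185 kHz, −40 dB edge ≈ 137 kHz | scaled probe band |
| ideal pulse | fc 80 kHz | hybrid low edge ≈ 27 kHz |
| phantom | r = 38 mm, fat 1450, glandular mean 1700 | ΔTOF ≈ 6–8 µs so the band-limited start band has N ≈ 0.8–1 (skips) while the broadband start band has N ≈ 0.25 (safe) |
| texture | 25 m/s, 7 mm correlation | feature size scaled with the inversion wavelength, as 5 mm texture is to a 1.2 MHz stop band at full scale |
| FWI bands | 45→210 kHz (broadband), 135→210 kHz (band-limited), 4 bands, 20 iterations | scaled analogue of 0.20/0.50→1.20 MHz; iteration budget sized for a single CPU core |
| noise | 2 % RMS band-limited Gaussian on band-limited inputs only | targets stay clean |

The glandular contrast is higher than typical tissue so the skip number
reaches ~1 at a frequency the 128² grid can resolve; it stays inside the
inversion clip range. The residual-resolution floor of the 210 kHz stop
band (sharp fat/gland edges under a λ/4 smoothing) is ≈ 0.19 of the
starting RMS; converged broadband inversions land at ≈ 0.21–0.23.

## Inversion

Frequency stepping low-passes (zero-phase Butterworth, order 6) *both*
the observed and the synthetic gathers at each cutoff, so both sides of
the misfit share the identical record-truncation and filter-edge path —
filtering only the source wavelet is equivalent in infinite time but
differs at the 0.1–2 % level on finite records, which is enough to leave
a spurious residual at the true model. The adjoint source is the
filtered residual passed once more through the (symmetric, hence nearly
self-transpose) filter.

The optimizer is preconditioned nonlinear conjugate gradient
(Polak–Ribière with restart on line-search failure), preconditioned by
accumulated source illumination `Σ_t p²`, with a backtracking line
search refined by a one-point quadratic fit. A band is stopped early
when its misfit falls below 1e−9 of the band's data energy (residual at
rounding level — important because float32 solver noise would otherwise
be "fitted") or when the line search fails after four halvings. The time
step is pinned from the SoS clip ceiling (1800 m/s) so every model the
search visits shares one discretization. Updates act on slowness
squared, are clipped to 1300–1800 m/s inside a circular inversion mask,
and leave the exterior at the water start. Raw (un-normalized) L2 is the
misfit; per-trace normalization exists as a flag but is not exercised.

## Bandwidth extension

Training pairs are 96×16 windows (time × element) cut from matching
(band-limited + noise, broadband clean) gathers at random shifts in
[−16, 16) with random element-order flips; the full-scale configuration
uses 256×96 windows and ±144 shifts, and the printed pool arithmetic
(3072 gathers, 294 912 traces, 7 077 888 augmented gathers over four
datasets) is exposed as `dataset_counts` / `augmentation_count`.
Windows are max-abs normalized per window, the target sharing the
input's scale.

Two architectures are trained with Adam on window MSE, on a compact
numpy layer engine with hand-written backward passes (verified against
central differences at < 1e−6): a depth-3, base-8 U-Net with
concatenated skips over the 2D windows, and the per-trace baseline —
five 1D convolution stages with PReLU and batch normalization. Inference
tiles full traces with 50 %-overlapping windows blended by Hann (+0.05
floor) weights. Training two phantoms × 192 windows for 15 epochs takes
about a minute per model on one core; at desk scale the U-Net removes
~65–70 % of the RMS error in bands below the input's −40 dB edge and the
1D baseline somewhat less, and FWI on U-Net-extrapolated data lands
between the broadband and band-limited extremes, preserving the ordering
broadband ≤ extrapolated < band-limited.

Trace noise is parametric band-limited Gaussian scaled to a target RMS
ratio. A learned (adversarial) noise generator would add realism for
hardware data but no testable mechanism for synthetic studies, so it is
out of scope.

## Calibration

Water-shot first-arrival times are compared with straight-ray
predictions `|x_r − x_s|/c_water`; probe poses (centre, orientation;
elements rigid at known pitch) are found by Gauss–Newton with a
Levenberg fallback, probe 0 gauge-fixed. Noise-free pose perturbations
of 2 mm / 2° are recovered to machine precision in ≤ 10 iterations, and
pose error grows linearly with pick noise.

The wavelet estimate NMO-aligns all traces of a source (Fourier-domain
fractional delays), stacks, trims to the energetic support, and
peak-normalizes. In 2D the received far-field waveform is the
half-*integral* of the injected source (the √f roll-off and −45° phase
of the cylindrical Green's function), so by default the stack is
half-differentiated to return the estimate to source convention;
`correct_2d_response=False` yields the raw received-pulse estimate. On
straight-ray synthetic water shots the stack correlates with the true
wavelet above 0.99 (0.95 at SNR 10 with ≥ 100 traces); on
finite-difference shots residual numerical dispersion limits the
correlation to ≈ 0.96–0.98.

## What desk-scale passes do and do not show

Passing tests demonstrate the *mechanisms*: adjoint correctness, the
cycle-skipping phase transition and its cure, the learnability of
in-distribution low-frequency extrapolation, and calibration-chain
correctness. They do not demonstrate transfer to real anatomy (the
phantom generator is statistical), robustness to out-of-distribution
noise or hardware effects (element directivity, 3D propagation,
attenuation), or the absolute RMS figures reported for full-scale
anatomical test sets, which require that data and GPU-scale training.

## Known limitations

* Constant density and no attenuation; air cavities are not modelled.
* The inversion assumes the source wavelet known (estimated separately);
  no source inversion.
* Inference-time window tiling is an invented necessity (how 256-sample
  windows tile full traces is not a published detail); the Hann-blend
  choice leaves a ≤ blend-tolerance seam on identity-trained models.
* The per-band Butterworth filter's transpose is approximated by itself;
  exactness holds only for the unfiltered gradient path (which is what
  the dot-product test certifies).
* The full-scale protocol (16×96 ring, 0.20/0.50→1.20 MHz, 208
  iterations, 256×96 windows) ships as a documented preset
  (`presets.PAPER`) but is not executed by the test suite.
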