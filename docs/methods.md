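# Methods

This note documents the models, estimators and numerical choices behind
flimcart, and what the synthetic phantom does and does not establish
about real cartilage data.

## Signal model

Each pixel of a scan is one digitized record of length 150 ns
(1875 samples at dt = 0.08 ns) containing three time-shifted fluorescence
decays, one per spectral channel, produced by the instrument's delay
fibers. Default channel delays are 4/54/104 ns with a 45-ns analysis
window per channel; the 4-ns pre-trigger region before the first channel
provides a pure-baseline segment, as digitizers conventionally record.
(A zero first delay would leave no pre-pulse region to estimate the
pedestal from.)

The measured decay in a window is `y = irf ⊛ h + b + ε`, where `h` is
the fluorescence impulse response of the tissue, `irf` a unit-area
Gaussian of 0.6 ns FWHM (the excitation pulse dominates the instrument
response), `b` the detector pedestal, and `ε` noise. Because generation
and analysis share the same iRF placement, recovered lifetimes are
referenced to excitation arrival without any explicit time-axis shift.

**Channel equalization.** The instrument equalizes the three channels'
detected intensity with neutral-density filters. The generator applies
known per-channel gains (default 2/9/1) so all channels reach the
detector at comparable amplitude — and hence comparable signal-to-noise —
and map assembly divides the gains back out before intensity ratios are
formed. Without this, the dimmest channel (channel 2, ratio ≈ 0.067)
would be ~10× noisier than the others, which is not how the real
instrument operated.

**Noise.** Per sample, `ε ~ N(0, σ₀² (1 + s/s_peak))`, with
`σ₀ = s_peak / 10^(SNR_dB/20)` and a default peak SNR of 40 dB: an
additive detector floor plus a Poisson-like signal-proportional term.
Per-pixel brightness varies lognormally (CV 0.1). These choices are the
package's own; no noise statistics were available to emulate.

## Average lifetime and its truth definition

The average lifetime is the expected value of the photon-arrival-time
distribution: `τ̄ = Σ tₙ hₙ / Σ hₙ`, `tₙ = n·dt`, evaluated over the
45-ns window. The generator defines its ground truth with the *same*
discrete, truncated definition: `synth_decay` builds, for each target
lifetime, a bi-exponential with fixed time constants 0.6τ̄ and 1.8τ̄ and
solves the mixing fraction so the discrete windowed mean equals the
target exactly (a mono-exponential variant solves its time constant by
root finding instead). This keeps truth and estimator on one definition,
so recovery errors measure the pipeline, not a definition mismatch.

## Laguerre deconvolution

The impulse response is expanded on discrete-time Laguerre functions
built by the standard causal recurrence. Two practical points:

* **Basis length.** Orthonormality and within-window decay of the
  functions only hold once the construction length exceeds the functions'
  support (≈1350 samples for α = 0.96, order 12). The basis therefore
  carries its own auto-grown length at which both invariants are
  verified (orthonormality to 1e-8, tail below 1e-3 of peak); since the
  recurrence is causal, restricting the basis to the first N samples of
  a data window reproduces exactly the matrix one would build at length
  N. Fits are unaffected; the invariants become meaningful.
* **Solver.** With design `A = irf ⊛ B` and QR factorization `A = QR`,
  the non-negativity-constrained least-squares problem is the Euclidean
  projection of `d = Qᵀy` onto the polyhedral cone `{u : G R⁻¹ u ≥ 0}`
  (G = rows of B, unit-normalized). By Moreau decomposition this equals
  `d + Mᵀμ*` where `μ* = argmin_{μ≥0} ‖Mᵀμ + d‖²`, `M = G R⁻¹` — a
  non-negative least-squares problem solved exactly by Lawson–Hanson
  NNLS. The unconstrained solution is used directly whenever it is
  already feasible (within 1e-9 relative), which is the common case on
  clean data; residual negative dust is clipped at zero.

**Constraints.** Non-negativity of `h` always. Map assembly additionally
enables a monotone non-increasing constraint by default: autofluorescence
impulse responses are sums of decaying exponentials, so monotonicity is
physically valid, and it suppresses the positive lifetime bias that
rectified tail noise otherwise produces in dim channels (measured on the
depleted channel-2 ROI: bias +0.09 ns without, +0.03 ns with). The
single-decay `deconvolve` keeps the constraint off unless requested.

**Order and scale.** Order 12 throughout. The scale α is calibrated per
channel by grid search over {0.90 … 0.98}, minimizing the mean relative
fit residual on an evenly spaced subsample of valid pixels. At realistic
SNR the residual is flat across all adequate alphas (the noise floor
dominates), so ties within 0.5% are broken toward the largest alpha,
whose basis has the longest time support and the smallest truncation
bias; on noiseless data the residual differences are decisive and the
search behaves as a true argmin. A fixed α may be passed instead.

**Baseline.** Single records subtract the mean of their own pre-pulse
region. Whole-scan processing pools the pre-pulse samples of all records
into one estimate (the pedestal is stable over a scan): a per-record
estimate from 50 samples carries enough error that, spread as a flat
offset over the 45-ns window (whose mean arrival time is ~22 ns), it
contributed ~0.5 ns of per-pixel lifetime scatter in dim channels.
Explicitly fitting a DC column in the deconvolution was tried and
rejected — it is nearly collinear with the slowest Laguerre components
at large α and tripled the variance.

**Intensity.** Integrated intensity is taken from the refit observation
`irf ⊛ h`, not the raw windowed sum, so zero-mean noise does not bias
the intensity ratios; the third ratio component is computed as the
complement so each triple sums to 1 exactly.

## Phantom tissue model

* **Geometry.** 50×50 pixels at 0.2 mm pitch (10×10 mm field) or 0.05 mm
  for depth profiling. The surface sits nominally 5 pixels deep with a
  one-pixel sub-pixel tilt across the field. A perfectly grid-aligned
  flat surface would quantize every layer thickness to whole pixels
  (0.7 mm is 3.5 px at 0.2 mm pitch, so truth itself would read 0.6 or
  0.8 mm); the tilt dithers the per-column counts so their mean equals
  the nominal thickness, and it exercises sub-pixel surface detection.
  Arbitrary surfaces (tilt, curvature) can be injected per preset.
* **Channel 1 depth profile.** Constant 5.7 ns over the first 0.1 mm
  (the superficial zone reads the superficial value), linear rise to
  6.1 ns at 0.5 mm, constant beyond. A strictly linear ramp from the
  surface was rejected because even a perfect pipeline then averages
  5.74 ns over the first 0.1-mm depth bin — the superficial reading
  would be wrong by construction rather than by measurement error.
* **Depletion.** GAG-depleted presets shorten channel 2/3 lifetimes by
  0.44/0.75 ns inside a surface-contiguous layer (0.3 mm "low", 0.7 mm
  "high") and leave channel 1 unchanged. The intensity-ratio triple
  switches from the healthy (0.323, 0.0670, 0.6100) to its element-wise
  product with (0.63, 0.69, 1.23), renormalized. Only the relative
  changes are constrained by the study; under simplex closure they admit
  a one-parameter family of control triples, and the chosen member puts
  healthy channel-1 ratio above, and depleted below, the 0.25
  segmentation threshold. The low preset shares the depleted optical
  properties and differs only in layer thickness.

## Geometry and segmentation

Surface detection takes, per column, the argmax of the axial gradient of
3-pixel-median-smoothed total intensity (ties toward the shallower row)
with parabolic sub-pixel refinement — the pitch (0.2 mm) is coarse
relative to the 0.5-mm ramp, so sub-pixel matters. Distances are
Euclidean from pixel centers to the piecewise-linear surface polyline,
correct on tilted surfaces; pixels above the surface get negative
distance and are excluded. Depth profiles bin at 0.1 mm by default and
report n, mean, SD, quartiles and extremes per channel.

Segmentation labels, per column, the contiguous run of valid pixels from
the surface downward whose channel-1 ratio is below threshold; isolated
deep sub-threshold pixels are not counted, matching surface-inward
biology. The default threshold 0.25 can be re-derived from ground truth
by `roc_threshold`, which sweeps all midpoints between sorted unique
values, computes AUC by trapezoid, and picks the Youden-optimal point
(ties resolved toward the midpoint of the class means). Group
comparisons delegate to scipy's one-way ANOVA and Tukey HSD
(studentized-range adjustment, family level 0.05).

## Problem sizes and determinism

All analyses run at desk scale: full 50×50 scans (7500 deconvolutions)
build in about a second, and the complete acceptance computation —
five phantoms plus a 100-replicate precision study — takes well under a
minute on one CPU. Identical configuration and seed give bit-identical
scans; map assembly, calibration and segmentation are deterministic
given a scan.

## What the phantom does and does not show

Passing recovery tests shows the pipeline is unbiased and precise under
the generator's assumptions: bi-exponential decays, a Gaussian iRF,
Gaussian-plus-Poisson-like noise, a clean PBS/tissue step, and piecewise
tissue homogeneity. Real cartilage adds fluorophore heterogeneity,
chromatic fiber dispersion, detector nonlinearity, photobleaching,
pile-up at the 4-kHz repetition rate, and histology-registration error —
none of which are modeled, and the generator's depleted layer has a
sharp boundary where real enzymatic depletion grades smoothly. Recovery
here validates the computational chain, not the biology.

## Known limitations

* Lifetime estimates in dim, noisy channels retain a small positive
  bias (≈ +0.02 ns at the defaults) from the constrained fit's boundary;
  ROI means inherit it.
* The ROC threshold and segmentation operate on a single parameter
  (channel-1 ratio); no multi-parameter classifier is provided.
* Depth profiles assume a single-valued surface per column (no
  overhangs), adequate for cross-sectional scans.
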