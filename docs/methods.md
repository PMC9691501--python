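# Methods

## The model

`bivision` implements a multi-stage model of the early visual pathway of
small flying insects, used as a detector for pixel-scale moving targets in
panoramic imagery viewed from a rotating platform. Two pipelines share the
first two stages and then split:

**Photoreceptor (PRC).** Per-pixel adaptive compression of linear
high-dynamic-range luminance into [0, 1). An intensity-driven first-order
low-pass (brighter pixels respond faster; corner mapped log-linearly from
luminance into 2–40 Hz over the range 10⁻²–10⁴ luminance units), a fast
divisive feedback loop (5 Hz) and a slow subtractive-exponential loop
(0.1 Hz) provide light adaptation over two time scales, and a hyperbolic-
ratio (Naka–Rushton) transform `v/(v + 0.5)` compresses the result. Both
feedback loops are seeded at their closed-form fixed points on the first
frame (quadratic root for the divisive loop, Lambert W for the exponential
one); seeding them from the raw first frame leaves the output shut down for
hundreds of frames, far beyond any reasonable warm-up.

**Lamina (LMC).** Spatio-temporal redundancy reduction: a leaky temporal
high-pass whose per-pixel corner follows the photoreceptor's slow
adaptation state (0.5–10 Hz), then a spatial centre-minus-mean high-pass
(radius 1). An optional `tanh` squash is off by default. The exact
functional forms mapping intensity to the PRC corner and adaptation to the
LMC corner are design choices (log-linear); the published model defers
these constants to earlier physiological fits, so every corner is exposed
in config.

**Motion pathway (EMD → MLI).** An opponent delay-and-correlate unit on
horizontally neighbouring lamina outputs, `delay(xᵢ)·xᵢ₊₁ − xᵢ·delay(xᵢ₊₁)`
with a 3 Hz first-order low-pass delay and wrap-around at the panorama
seam. The pooling stage rectifies, box-averages over 5×5 px and smooths in
time with a first-order low-pass — the published corner is 0.453 Hz, the
tuned preset 4.0 Hz. This pre-normalisation tap `E_MLI` is the lateral-
inhibition signal; its frame mean is the global motion estimate, a
deliberate simplification of the insect's wide-field integrator.

**Target pathway (RTC → ESTMD).** The rectifying transient cell high-pass
filters its input (1 Hz), splits it by half-wave rectification into ON and
OFF channels, and subtracts a per-channel adaptation state that snaps to
the one-frame-delayed channel value when the temporal derivative exceeds a
threshold (0.01 per frame in lamina units) and otherwise relaxes through a
0.5 Hz low-pass — fast adaptation to rises, slow refractory decay. A 5×5
centre-minus-surround inhibition (surround normalised so a uniform patch
maps to zero) suppresses extended bars and flicker. The small-target
correlator multiplies, per pixel, one channel with the 3 Hz-delayed other:
`dark = delay(off)·on`, `bright = delay(on)·off`. The snap-to-delayed-value
adaptation rule and per-channel surround inhibition are explicit choices
where the published description is underdetermined.

## Lateral inhibition

The tap is conditioned with `E_c = min(G·E/(E + c), 1)` (defaults
G = 1.1, c = 0.02; c = 0.008 and 0.04 ship as presets for man-made and
purely natural scenes), inverted to a suppression factor `s = 1 − E_c`,
and injected at any subset of four locations:

- **A** multiplies the single pre-RTC signal;
- **B** rescales the RTC derivative threshold by the same factor,
  restoring triggering for transients attenuated at A (B therefore
  requires A);
- **C** multiplies the two rectified channels separately;
- **D** multiplies the two correlator outputs (one shared map).

The product form `y = x·s` is algebraically identical to
`max((xc − x(G−1)E)/(E + c), 0)`; the test suite asserts the identity to
1e-12. The earlier linear scheme conditions the tap as `min(6·E, 1)` and
injects at A and D. With `E_MLI ≡ 0` every variant reduces exactly to the
uninhibited model.

In dynamic mode the half-saturation is recomputed every frame from the
global motion estimate m via `c = 0.013488·ln(m) + 0.05514`, clamped below
at `c_floor = 1e-4` because the law goes non-positive for very small m
(an out-of-domain regime for the fit; the clamp is the safe completion).
`fit_dynamic_coeffs` recovers the coefficients of this law from
(motion, best-c) pairs by least squares on ln(motion).

**Units.** The motion tap has no absolute physical unit; the constants
above presume a particular scale. The detector gain (`flow_gain = 117`)
calibrates the tap so that the frame-mean pooled motion on the cluttered
reference condition (synthetic scene at clutter gain 3, matched speeds
29 px/s) is ≈ 0.05 — the mean-local-motion operating point around which
the conditioning constants are specified. All inhibition constants inherit
their meaning from this anchor.

## Scene simulation

Scenarios are rendered at 8× the working resolution (reference protocol:
8000×1600 panorama spanning 360°×72°, decimated to 1000×200, i.e.
0.36°/px), at 100 frames/s. Black 1.2 px targets (≥ 10 px apart) and the
background rotate right-to-left at speeds from {10, 17, 29, 50} px/s.
Gaussian blur is applied at full resolution with σ chosen so the decimated
point-spread FWHM is 1.0 px (FWHM = 2√(2 ln 2)·σ), then frames are
decimated by nearest-neighbour sampling at offset 0. Sub-pixel motion uses
linear interpolation at full resolution; when target and background speeds
match, the blurred composite is translation-invariant, so it is built once
and shifted per frame (exact, since periodic interpolation and convolution
commute). Ground truth is emitted as continuous decimated coordinates.
Note the blur FWHM describes the point-spread function, not the rendered
dip of a 1.2 px target, whose profile is correspondingly wider (≈1.4 px).

**Synthetic panoramas.** The original measured panoramas are not
redistributable, so the generator synthesises scenes with natural-image
statistics: log-luminance is a random-phase field with 1/f amplitude
(1/f² power), split into three bands — large-scale illumination (below
1/45 cycles/degree, unmodulated: sky/ground variation), mid-band
structure, and high-frequency clutter (above 0.5 cycles/degree). The two
structured bands are multiplied by a smooth random envelope (sigmoid of a
very-low-frequency field) so clutter forms patches against otherwise
featureless regions, as vegetation and buildings do against sky and open
ground. This heterogeneity is essential: a clutter-adaptive suppression
mechanism is vacuous on spatially homogeneous texture, where it attenuates
targets and distractors alike. The modulated bands are rescaled by the
reciprocal RMS of the default-coverage envelope so that, at the default
gain, the radially averaged power spectrum continues the 1/f² law across
bands while sparse patches carry ≈3–4 log-units of local contrast (deep
shadow gaps beside bright glints, as in high-dynamic-range foliage).
`clutter_gain` shifts the envelope bias by −ln(gain), widening clutter
coverage; the band amplitude stays frozen, so higher gain monotonically
raises the high-band spectral magnitude. The field is exponentiated into
strictly positive luminance (mean 100, log-contrast 0.5). The 1/f² slope
is asserted on log-luminance: exponentiation into linear HDR radiance
whitens the linear-luminance tail with sparse glints, as it does in real
HDR imagery.

What the generator does **not** emulate: oriented structure (edges,
horizons), occlusion geometry, non-Gaussian phase statistics of real
texture, photon/sensor noise, and vertical camera motion. Passing the
directional tests on these scenes shows the inhibition mechanism behaves
as designed under controlled, heterogeneous clutter; it does not certify
performance on any particular real imagery.

## Evaluation protocol

Models warm up for 300 frames (the slowest loop, 0.1 Hz, has τ ≈ 1.6 s);
the following evaluation frames are scored. A winner-take-all pass keeps
strict local extrema of a 7×7 neighbourhood (maxima of the dark-target
channel; minima for the signed local-contrast baseline), ties keeping the
lexicographically first position. Detections are matched greedily (highest
score first, one detection per target per frame) within a 5×5 window
centred 1 px right of the true centre for the temporally correlating
models — right-to-left motion puts the response on the trailing edge — and
unshifted for spatial-only methods, with horizontal wrap. A threshold
sweep yields per-frame mean TP and FP counts; the headline score
integrates TPR over the FP axis from 0 to 20 FP/frame (trapezoidal, curve
extended horizontally) and divides by 20, so scores lie in [0, 1].

Clutter metrics: MCPP is the mean over pixels of 3×3 neighbourhood
standard deviation over neighbourhood mean (the cited definition is not
printed; local RMS contrast is this package's reading); MFM is the mean
2-D spectral magnitude in the 2–2.7 px/cycle band, the resolution-
independent form of 1.044–1.389 cycles/degree at the reference 0.36°/px
(at coarser scaled-down sampling the angular band is empty, the pixel
band is not).

**Local-contrast baseline.** The single-scale contrast map is centre-cell
mean minus the maximum of the eight surrounding 3×3 cell means — a signed
difference form (dark targets give negative contrast), deviating from the
original ratio formula so that minimum-seeking winner-take-all applies.
For the baseline-with-inhibition experiment, the suppression comes from a
statically conditioned motion branch whose pooling window is widened to
9×9 to match the contrast kernel's spatial footprint; with 5×5 pooling the
suppression map is narrower than the comparator's response support and
partially suppressed patch rims dominate the false positives.

## Reduced-scale study conditions

The shipped experiments (acceptance script, directional tests) run at
256×64 working resolution (2048×512 full) with 40 targets — the same
target density, decimation factor, blur, speeds and warm-up as the
reference protocol, with 60 evaluation frames; a full-scale scenario is a
config change away. Three experiments:

- **Variant ladder** (clutter gain 3, matched speeds 17 and 29 px/s, five
  seeds each): median AUROC orders tuned-nonlinear ≥ nonlinear ≥ linear ≥
  uninhibited.
- **Baseline inhibition** (gain 1, both speeds, five seeds): median AUROC
  of the contrast baseline with inhibition ≥ without.
- **Clutter direction** (gains 1/2/4, three seeds, 29/29): median AUROC of
  the uninhibited model decreases while MFM increases.

## Numerical choices

- Temporal recursion `y += α(x − y)` with `α = Δt/(τ + Δt)`,
  `τ = 1/(2πf_c)`; corners are validated against the Nyquist limit.
  First frames seed filter states (and feedback fixed points) to avoid
  start-up transients.
- Boundary convention everywhere: horizontal wrap (360° panorama),
  vertical replicate.
- The sliding-sum box filter can return values an epsilon below zero;
  rectified quantities are clamped at 0 before entering saturating
  nonlinearities.
- Winner-take-all requires the window maximum to exceed the window
  minimum, so constant regions yield no detections.
- The dynamic-c law falls back to the static c when the global motion
  estimate is non-positive.

## Known limitations

- Constants inherited from prior physiological work (PRC/LMC corner maps,
  RTC thresholds, EMD delay) are order-of-magnitude choices exposed in
  config, not refits of the original data.
- The motion tap's absolute scale is anchored to the synthetic reference
  scene; on measured panoramas `flow_gain` (or c) may need re-anchoring to
  the same mean-motion convention.
- Only horizontal rotational ego-motion and black targets are simulated;
  the elaborated multi-stage motion detector and the wide-field
  tangential-cell ego-motion stage are out of scope (the global estimate
  is a frame mean).
- ROC aggregation uses per-frame mean operating points; pooled counts
  would differ slightly at equal thresholds.
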