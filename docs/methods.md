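# Methods

This note documents the models, conventions, numerical choices, and known
limitations of the package. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The method in brief

A fully convolutional network is trained on a *single* unlabeled crop of one
object. Each mini-batch consists of `K = 8` views of that crop, produced by
randomly sampled transformations (translations, rotations, reflections; for
holographic data also numerical refocusing and signal rescaling). The network
outputs, at stride `k = 2`, two displacement planes `dx, dy` and a logit
plane `rho`, plus one optional plane per extra symmetry. Decoded position
maps are

    x_ij = dx_ij + i k − N/2,      y_ij = dy_ij + j k − M/2,

with `N, M` the *input* dimensions (a companion accessor shifts to the
top-left pixel-center convention used for all reported positions). The
weight map is the elementwise sigmoid of `rho`, normalized to sum to one;
the pooled prediction is the weight-averaged position (and extras).

Training minimizes the sum of two L1 losses: the deviation of the
inversely-transformed pooled predictions from their batch mean, and the
weighted spread of each decoded map around its own pooled value. During
training the weight map receives 1% dropout and an `eps = 1e-6` floor before
normalization, which prevents single-pixel collapse. Because an equivariant
predictor on an object with a rotational symmetry must output the symmetry
center, the network learns sub-pixel localization with no labels at all.

Multi-object detection removes the global pooling: the decoded maps are
combined with a clustering metric `b` (inverse of the summed local 3×3
variance of the decoded channels) into a score map `w^alpha b^(1-alpha)`;
prominent local maxima above a score quantile are candidate detections, each
refined by a weighted average of the decoded maps in a small window.

## Conventions and defaults

| parameter | default | notes |
|---|---|---|
| image coordinates | 0-based (row, col) px from the top-left pixel center | `x` is the row axis |
| intensity SNR | `(peak − background)/sqrt(background)` | background 100 expected photons |
| shape geometry | point: Gaussian σ=2 px; sphere: disk r=6 ⊛ σ=1; annulus: 4–7 ⊛ σ=1; ellipse: 8×4 ⊛ σ=1; crescent: disk 7 minus disk 5 offset 3, ⊛ σ=1 | all configurable |
| rendering | 10× supersampled, analytically anti-aliased edges, box-integrated | flux is translation invariant to ≲0.1% |
| network | 3 conv (3×3×32, ReLU) + 2×2 max-pool + 8 conv + 1×1 linear head | the Methods-grade variant of the architecture; a shallower 2+7 variant is configurable |
| training | Adam, lr 1e-3, 5000 mini-batches of 8 views | 15000 batches for the axial task in the original protocol |
| transforms | translations U(±8 px), rotations U[0, 2π), reflections Bernoulli(½) | dz U(±2 µm) and ln s U(±ln 4) when the respective symmetry is enabled |
| loss weights | L_a + L_b, unweighted | presented as joint objectives without coefficients |
| input normalization | intensity crops divided by their mean; complex fields fed as (Re−bg, Im−bg) planes | background-referenced planes keep the scale signal |
| detection | α=0.1 (homogeneous particles; up to 1 for variable morphologies), β=1−α, quantile 0.99, prominence 1e-3×max, window 3, ε_b=1e-6 | see below for the window choice |
| holographic optics | 633 nm, NA 1.3, pixel 114 nm, n_medium 1.33, n_oil 1.5 | angular-spectrum propagation, carrier-referenced |
| trace linking | per-frame-pair linear sum assignment, 1 µm gate, ≥40-frame filter for noisy data | |
| polarizability | Clausius–Mossotti `3V (n_p²−n_m²)/(n_p²+2n_m²)`, real part | calibrated against a known population |

## Design choices where the design was open

**Scale-transform range.** The signal-rescaling symmetry only teaches the
log-scale channel inside the trained range. The quantification grid used for
validation (radii 180–280 nm, indices 1.45–1.65) spans polarizability ratios
of roughly 0.24–2.3 relative to the 228 nm training particle, so the package
default is `ln s ~ U(−ln 4, ln 4)`. A narrower ±ln 2 range leaves both grid
corners outside the trained symmetry and visibly compresses the channel's
response.

**Refinement window.** The sub-pixel refinement window must stay below half
the minimum object separation, otherwise the weighted average merges
neighbouring objects into one midpoint detection. With compact holographic
point responses and particles allowed as close as ~10 px, a half-width of 3
feature-map px (6 input px) is the default.

**Evaluation SNR for polarizability quantification.** Under the field-SNR
convention `max|I| / sqrt(σ_Re² + σ_Im²)`, the background (≈1) dominates
`max|I|`, so the noise floor is effectively background-referenced while the
weakest grid cell scatters only ≈7% of the background amplitude. The
quantification experiments therefore run at SNR 60, where quadrature noise
stays below ~1/5 of the weakest signal — the regime in which amplitude
estimation is meaningful. At SNR ≲ 30 the weakest cells are noise-dominated
and their percentage errors are essentially unbounded; this is a property of
the signal, not of the estimator.

**Modulated-setup replica.** Sample-position-modulated holography subtracts
offset frame pairs, cancelling the static background while retaining the
(low) particle signal and the full noise floor. The replica simulates fields
with `background = 0` and the same field-SNR convention applied to the
particle signal itself.

**Axial channel units.** The z channel is trained directly in microns: the
inverse transform subtracts the sampled propagation distance in µm, so the
channel's gauge is metric from the start. The oil/water apparent-depth
correction (×1.128) is applied only when a medium/immersion mismatch is
declared.

**Anchor convention.** Rotations (of images, and of predictions during loss
inversion) are taken about the crop center at pixel coordinate
`((H−1)/2, (W−1)/2)`. The training loss is what defines the network's
absolute position gauge; evaluation uses the same top-left decoding
everywhere.

## Numerical engine

The network, backpropagation, and Adam are implemented directly on numpy:
convolutions are im2col + single-core BLAS GEMMs (float32, channels-last),
the input gradient of a 3×3 convolution is computed as a same-padded
correlation with the spatially flipped, channel-transposed kernel, and
max-pool ties share their subgradient equally. The closed-form gradient of
the full training loss (both L1 terms, the dropout/eps weight normalization,
and the inverse-transform mapping of pooled predictions) is verified against
central finite differences in the test suite to ~1e-6 relative for the loss
head and float32 precision for the conv stack.

## What the synthetic generator does and does not emulate

The intensity generator produces anti-aliased expected-photon images of five
shape families with Poisson shot noise under the SNR convention above; it
does not model read noise, EMCCD gain, aberrations, or vectorial PSFs. The
holographic generator is a *weak-scatterer* model: each sub-wavelength
sphere contributes `i·s` times a diffraction-limited (hard-aperture) complex
point response, refocused by angular-spectrum propagation, with `s`
proportional to its Clausius–Mossotti polarizability; noise is additive
complex Gaussian. Consequently particles of different radius and index
differ *only* in amplitude, which makes the scale-equivariance task cleaner
than Mie-accurate imagery; passing tests demonstrate the mechanism, not
Mie-level photometric accuracy. Multiple scatterers superpose linearly
(no multiple scattering, no off-axis carrier fringes — fields are stored
demodulated).

## Problem sizes used by the tests and the acceptance script

Training runs are desk-scale (the full protocol is 5000 mini-batches, 15000
for the axial task): the acceptance script trains the point model for 1600
mini-batches on a 48×48 crop, the scale-symmetric hologram model for 2000,
the modulated-replica model for 800 (40×40 crop), and the axial-symmetry
model for 2000; the test suite trains the five shape models for 700–2500
batches on 40×40 crops and the holographic models for 500–1500. Evaluation
sets are 500 images for the point sweep, a 5×5 condition grid × 4 repeats
for polarizability at field-SNR 60, and 4–10 multi-particle scenes per
condition for detection F1 with a 2 px matching gate (bi-dispersed sweep at
field-SNR 30/50/80). Loss curves show the pooled-consistency loss still
slowly decreasing at these budgets; longer runs tighten the anchor (see
Limitations).

## Known limitations

* **Information floor of the point task.** Under the declared photometry
  (PSF σ=2 px, background 100), the Cramér–Rao bound for the point shape is
  ≈0.096 px at SNR 10 and ≈0.095 px RMS-aggregated over SNR ~ U(5, 20] — the
  package's CRLB oracle computes these directly. Any reported RMSE for this
  task should be read against that floor.
* **Anchor drift.** Training on a single noisy image anchors the detector to
  the compound (object + frozen noise) pattern; with a constant learning
  rate the anchor also performs a slow random walk under mini-batch noise.
  Both effects contribute a bias of the order of the single-image
  localization error.
* Edge effects: the pooled prediction sums over the whole feature map; when
  the object signal is very weak the weight map can latch onto border
  artifacts of the zero-padded convolutions.
* The weak-scatterer hologram model is not Mie theory; absolute polarizability
  is meaningful only after calibration, and radius/index enter only through
  the scattering amplitude.
* Trace linking is nearest-assignment only: no gap closing, no merge/split
  handling, no motion model.
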