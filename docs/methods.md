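# Methods

This note records the model, the parameter choices and their rationale,
what the synthetic phantoms do and do not emulate, and the numerical
decisions a maintainer would otherwise have to reverse-engineer from the
code. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The contour-aligned (ST) transform

A rib boundary is a closed, simple, piecewise-linear contour in pixel
coordinates (pixel-center convention, 0-based, x = column). The transform
is defined through its inverse, T⁻¹(s, t) = γ(t) + s·n̂(t): t is arc length
along the contour (wrapping modulo the contour length, each edge owning the
half-open interval [t_i, t_{i+1})), s the perpendicular offset with **s > 0
pointing inward** — the algorithm marches from the boundary toward the
centerline, so the inward direction is the natural positive axis. The
forward map projects a point onto every edge, keeps the candidates whose
perpendicular foot lies within the edge segment (each edge offset
independently along its own normal; strongly concave corners are outside
the intended geometry of rib bands), and selects the smallest |s|, ties to
the lowest edge index. Points in a corner fan, where no foot lands on any
segment, fall back to the nearest vertex.

Known discretisation behaviour, quantified in the tests: on a regular
n-gon approximating a circle the mapping converges to polar coordinates
with t error ≈ π·s/n, and the round trip forward∘inverse is exact except
within ~one ownership-tolerance of the medial axis, where the nearest-edge
assignment becomes degenerate (branch points of the medial axis, e.g.
where a straight side meets an end cap). Tests therefore sample in-band
points up to 0.75·(c(t) − slack).

**Centerline.** c(t) is computed by marching inward in 0.25-px steps and
keeping the longest prefix whose points (a) remain inside the filled rib
mask (bilinear membership with a generous 0.25 threshold, so sub-pixel
points hugging the rasterised boundary count) and (b) are still nearest to
their own side of the contour, with a slack of half a step plus 0.25 px for
the lateral drift of columns rooted near polygon vertices. The raw profile
is smoothed with a 5-column circular moving average to suppress
rasterisation jitter; zero-thickness columns are flagged invalid. This is
an operational definition: the quantity is the medial depth of the band,
and the mask+ownership march is how we make it total and deterministic.

**Sampling.** Band resampling uses `scipy.ndimage.map_coordinates`.
`sample_to_st` defaults to bilinear interpolation; the extraction pipeline
requests cubic splines (`ExtractionParams.interp_order = 3`) because the
bilinear interpolation bias on the curved taper of a shadow profile is the
single largest recovery-error term at 1-px sampling (measured on phantoms:
~6% vs ~4% relative RMSE). Default steps ds = dt = 1 px match the source
resolution; the phantom-recovery tests run at 0.5 px, which buys a little
accuracy at 4× cost. Rasterisation back to image space splats each valid
ST cell at its inverse-mapped position with bilinear weights, normalises by
accumulated weight, and fills uncovered mask pixels from the nearest
covered pixel.

## Bone extraction

The stages follow the gradient-domain recipe exactly: backward difference
along s (row 0 set to 0), masked and normalised Gaussian convolution along
t with circular wrap (t is cyclic), cumulative reintegration along s, and
KNN centerline smoothing applied in increasing s using the original
values. Numerical decisions:

- **Gaussian width.** Default 𝓀_t = (contour length in samples)/20 — "large"
  relative to soft-tissue variation along the contour but still local. It
  is the dominant per-image tunable: too small leaks background gradients
  into the bone estimate, too large blurs genuine amplitude variation
  along the rib.
- **Reintegration.** Two modes. `"cumsum"` (extraction default) adds each
  smoothed backward difference once; since the backward difference *is*
  the integral of the profile over [s−1, s], this inverts it exactly.
  `"trapezoid"` (the stage function's default) averages consecutive
  gradient samples and therefore reconstructs the half-sample-lagged
  profile (B(s)+B(s−1))/2 − B(0); it is kept because it is the
  conventional quadrature reading and some callers may want it, but it
  costs a systematic half-sample smear on steep tapers.
- **Lead-in margin.** `s_lead = 1.5` px are sampled *outside* the contour
  and included in the integration (but not rasterised back). The
  integration constant is thereby anchored where the shadow truly
  vanishes; without it, the value the rasterised shadow already has on the
  contour itself (a half-pixel boundary effect of any pixel grid) is
  unrecoverable from gradients.
- **Centerline KNN.** The rule keeps a value when its ratio to the inward
  predecessor exceeds τ and otherwise replaces it with the mean of its
  k = 5 predecessors (window clipped at the contour, renormalised; a zero
  predecessor counts as kept). With this branch direction, τ must sit
  *below* 1: the default τ = 0.8 passes monotone and flat profiles
  untouched and smooths only abrupt drops — which is what the centerline
  artifact looks like. Values of τ > 1 average away every profile that
  grows slower than τ per sample, including the flat top of a real
  shadow; a config switch (`keep_if_ratio_gt=False`) inverts the branch
  for experimentation.
- **Clamp.** The rasterised estimate is clamped at zero: an additive bone
  shadow is non-negative. The soft image is deliberately *not* clamped.

## Rib removal

Subtraction is exact pixelwise. The border band rb is the in-band strip
0 ≤ s ≤ s_b (default s_b = 3 px), rasterised by splatting the ST sub-band;
each band pixel is replaced by the mean of its k_border = 9 nearest pixels
(Euclidean, image space) drawn from the band plus a 2-px outer margin, so
context from both sides of the cut pulls a residual offset together.
k_border = 1 is the identity. A ribcage is processed sequentially in label
order L1..Ln, R1..Rn on the running soft image, so crossing ribs are
subtracted once each; disjoint ribs commute. Consequences that the tests
assert: soft + Σ bone equals the input exactly outside the border bands,
and pixels beyond every band and mask are bit-identical to the input.

The hyperparameter search draws `n_draws` combinations uniformly *without
replacement* (a seeded permutation of the product grid), so a draw count
equal to the grid size is exactly exhaustive enumeration. The objective —
the mean squared s-gradient of the soft image resampled inside the rib
bands — is a stand-in for whatever criterion the original per-image tuning
used, which is not recorded anywhere; it measures residual rib-edge energy
and is zero for a perfectly flattened band.

## Synthetic phantoms

A phantom is the exact decomposition input = background + bone + noise.

- **Background**: a seeded Gaussian white-noise field blurred at scale
  ~H/5, mean-centred, scaled to ±0.10 about a base level of 0.45 — a
  smooth, featureless stand-in for projected soft tissue.
- **Ribs**: curved constant-thickness bands (default 9 px) with
  semicircular end caps, gentle arcs (bow capped at a quarter of the span
  so the curvature radius stays far above the half-thickness), laid out as
  a vertical stack or as two L/R columns ("ribcage", up to 2×10). The
  additive shadow at a pixel is amplitude × profile(1 − d/half), with d
  the distance to the centerline polyline: because the boundary is the
  offset curve of the centerline (caps included), the shadow is constant
  along contour-parallel curves *by construction* — the modelling
  assumption of the physical algorithm, fabricated deliberately. The bone
  field is computed from centerline distances, not via the ST transform,
  so ST-based constancy checks remain independent. Default amplitude 0.15
  of unit range; cross profile "cosine-taper" (smooth rise over the outer
  half of the band, flat top) so the additive model is differentiable at
  the boundary; a "flat" profile is retained as a stress case with a
  non-differentiable edge.
- **Noise**: additive Gaussian, σ = 0.002 — radiographs at screening dose
  are high-SNR, and the phantom's purpose is to isolate the geometry, not
  to model detector statistics.

What passing on phantoms does **not** show about real CXRs: real rib
shadows vary along the rib (the constancy assumption holds only
approximately), backgrounds contain vasculature and anatomy with gradients
along the normal direction, rib borders are soft, annotations are
imperfect, and posterior/anterior ribs overlap with differing intensities.
The phantoms emulate none of these; they verify the machinery under the
model's own assumptions, where the right answer is known exactly.

Dataset export writes 16-bit PNG pairs after a common affine scaling to
[0, 65535] (the scaling recorded in the manifest), with the float
decomposition kept alongside as the canonical test surface so PNG
quantisation never silently dominates a tolerance. The 4:1 train/validation
split (245 → 196/49) mirrors the standard split of the rib-segmentation
corpus this pipeline is designed to pair with.

## Network and loss

The dense wiring of layer l concatenates 1×1-remapped outputs of layers
0..l−2 (each remap emitting max(1, ⌊C(x_{l−1})/(L−1)⌋) channels, the floor
at 1 guarding 1-channel inputs) with the raw output of layer l−1, then
applies BN → ReLU → 3×3 convolution. No pooling, striding or resampling
anywhere: every feature map keeps the input's H×W. The default schedule
(16, 32, 64, 128, 64, 32, 1) is a symmetric rise-and-fall chosen at desk
scale; the exact schedule is configurable, and tests exercise three.

Loss conventions, fixed so tests can be exact: the PSNR term is
log₁₀(MAX_X²/MSE) *without* the conventional factor 10 (a `psnr_times_10`
flag restores it); MSE is guarded below by 1e-12 so identical images stay
finite; the MS-SSIM term is 1 − (luminance at the coarsest scale) ×
(product over the five scales of spatially averaged contrast-structure
terms), with no per-scale exponent weights; stability constants
c1 = (0.01·S)², c2 = (0.03·S)² with S the dynamic range (1.0 for
unit-normalised floats, the canonical internal domain). Local statistics
use zero-padded Gaussian windows — symmetric kernel plus zero boundary
makes the blur self-adjoint, so the backward pass is the same blur applied
to the gradient, exact rather than approximate.

Since no autodiff framework is part of the dependency set, the network and
loss run on a small reverse-mode engine written for this package
(`sadxnet/autodiff.py`): ~15 operations (broadcast arithmetic, conv via
im2col + matmul, batchnorm with the standard closed-form backward, Gaussian
blur, reductions), gradient-checked end to end against central finite
differences in the test suite. It is float64, single-threaded numpy —
adequate for the desk-scale corpora the phantoms produce, not for
full-resolution clinical training.

Training uses Adam at an initial learning rate of 0.001 (maximum 200
epochs, batch 1 by default), records per-epoch mean training
loss and validation RMSE, and restores the best-validation checkpoint — or,
when no validation set is given, the best-training-loss state, because the
late training of a small net under the log-scaled PSNR term oscillates and
the final epoch is frequently not the best one. A non-finite loss aborts
with the epoch and batch in the message. Problem sizes in the tests and the
acceptance script (8 pairs at 64×64, 30 epochs; a 200-epoch single-pair
overfit; the (8, 16, 32, 32, 16, 8, 1) schedule) were chosen as the scale at
which this numpy engine trains a meaningfully dense model in minutes; the
overfit probe reaches roughly a quarter of the input-vs-truth RMSE at this
scale, not an arbitrarily small floor.

## Degenerate inputs and tie-breaks

Contours with fewer than 3 vertices, zero-length edges or
self-intersections are rejected at load with the offending label. A
duplicated closing vertex is dropped. CW and CCW orientations are both
accepted (inward normals are derived from the signed area). Zero-thickness
centerline columns are flagged invalid and excluded from smoothing.
Forward-map ties go to the lowest edge index; KNN windows clipped at the
contour renormalise their mean; a zero denominator in the centerline rule
counts as "keep". Empty contour lists yield identity suppression results;
an empty valid band raises an error naming the rib.

## Known limitations

- The ownership march makes c(t) total but tolerance-inflated by up to
  ~0.4 px; near medial-axis branch points the forward map is genuinely
  discontinuous, which is intrinsic to the transform, not a bug.
- Background gradients along the normal direction leak into the bone
  estimate at first order; the t-smoothing only cancels what varies along
  the contour. On phantoms this is ~1% of the rib amplitude; on real
  anatomy it will be worse and is what the per-image HP search is for.
- The ratio-threshold KNN centerline rule interacts poorly with non-monotone
  profiles for τ > 1 (see above); the default τ = 0.8 is safe for additive
  shadows but the rule remains a heuristic.
- The numpy training loop is two to three orders of magnitude slower than
  a GPU framework; it demonstrates and tests the architecture and loss,
  it does not reproduce full-scale training.
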