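# ribsuppress

Physical rib-shadow suppression for chest radiographs, plus a dense
denoising network that learns the suppression from the pairs the physical
model generates.

Ribs superimpose bright, elongated shadows on the lung fields of a chest
X-ray (CXR) and obscure the soft tissue beneath them. `ribsuppress`
implements an unsupervised *physical* suppression algorithm that removes
those shadows given per-rib boundary contours, a *synthetic phantom
generator* that produces radiograph-like images with exactly known
soft-tissue/bone decompositions, and a *supervised denoising network* that
can be trained on (raw, suppressed) pairs so new images are suppressed in a
single forward pass with no annotations.

## The method

**ST smoothing.** Each rib boundary is a closed piecewise-linear contour
C. The transform T_C maps an image point to contour-aligned coordinates
(s, t), where t is arc length along C and s the inward perpendicular
offset, via its inverse T_C⁻¹(s, t) = γ(t) + s·n̂(t). Inside the band the
rib's iso-intensity curves run parallel to the contour, so in ST space the
shadow is (ideally) constant along t. The bone shadow of one rib is then
estimated by

1. resampling the band I_st(s, t) up to the centerline depth c(t) — the
   locus where inward offsets from opposite sides of C meet;
2. differentiating along s: I_d(s, t) = I(s, t) − I(s−1, t), which a
   structure oriented along t does not enter;
3. Gaussian-smoothing I_d along t with a large kernel 𝓀_t, averaging away
   soft-tissue gradients while preserving the contour-constant rib
   gradient;
4. reintegrating along s from the contour (where the shadow vanishes)
   toward the centerline;
5. K-nearest-neighbour smoothing along s with ratio threshold τ, which
   flattens the artificial edge left at the transform's centerline
   singularity;
6. rasterising back to image space and clamping: I_bone = max(C(I_r), 0).

The soft-tissue image is I_soft = I − I_bone, with a KNN blend over the
thin border band s ≤ s_b to hide the cut, repeated rib by rib over the
ribcage. The per-image hyperparameters (𝓀_t, τ, neighbour counts, s_b) can
be tuned by a seeded random grid search against a residual rib-edge energy
objective.

**SADXNet.** The companion network treats the rib shadow as structured
noise: seven densely connected layers (each layer receives 1×1-remapped
feature maps of all earlier layers plus its predecessor's output), each a
BN → ReLU → 3×3 convolution composite, spatial resolution preserved
throughout, channel schedule rising then falling to a single output
channel. It trains with Adam (lr 0.001) under the composite loss

L = −α·L_PSNR + (1−α)·[β·L_MS-SSIM + (1−β)·L1],  α = 0.75, β = 0.25,

with L_PSNR = log₁₀(MAX_X²/MSE), a multi-scale SSIM term over Gaussian
window scales [0.5, 1, 2, 4, 8] px, and the mean absolute deviation. The
evaluation metric is RMSE against the physically suppressed ground truth.
The network and its reverse-mode gradients are implemented directly over
numpy (`ribsuppress.sadxnet.autodiff`), gradient-checked against finite
differences.

## Worked example

```python
import numpy as np
from ribsuppress.phantom import PhantomSpec, generate
from ribsuppress.rib_removal import suppress_ribcage
from ribsuppress.sadxnet import rmse

spec = PhantomSpec(size=(256, 256), n_ribs=6, seed=42)
sample = generate(spec)                      # input = background + bone + noise
result = suppress_ribcage(sample.input, sample.contours, sample.masks)

print(f"raw  vs ground truth RMSE: {rmse(sample.input, sample.background):.5f}")
print(f"soft vs ground truth RMSE: {rmse(result.soft, sample.background):.5f}")
```

prints

```
raw  vs ground truth RMSE: 0.05064
soft vs ground truth RMSE: 0.00242
```

i.e. the physical model removes ~95% of the rib signal (RMSE measured on
unit-range intensities; the residual 0.00242 is ~1.6% of the 0.15 rib
amplitude). `result.per_rib_bone` holds each rib's estimated shadow,
`result.log` per-rib diagnostics, and `result.soft + result.bone_total`
reproduces the input exactly outside the blended border bands.

The same pipeline is scriptable from the shell:

```bash
ribsuppress --seed 7 phantom --n 8 --out data/          # synthetic pairs
ribsuppress suppress --image scan.png --contours ribs.json --out out/
ribsuppress search --image scan.png --contours ribs.json --out tuned/
ribsuppress train --pairs data/ --epochs 30 --out model/
ribsuppress predict --image scan.png --checkpoint model/checkpoint.npz --out pred/
ribsuppress eval --pred pred/prediction.png --gt gt.png
```

Rib annotations are JSON polygon lists
(`{"ribs": [{"label": "L1", "vertices": [[x, y], ...]}]}`, pixel
coordinates, 0-based) or indexed-PNG label masks (background 0, ribs
1..40), as produced for rib-segmentation datasets.

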