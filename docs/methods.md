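# Methods

## Problem and model

`surf2vol` reconstructs a full CT-like volume `Y ∈ R^(H×W×L)` from a
voxelized body-surface image `X` of the same shape in which only the voxels
on the body's outer shell keep their Hounsfield intensities; everything
inside and outside the shell is set to a background value (air, −1000 HU by
default). The mapping is learned **per patient** from that patient's own
respiration-resolved series (10 phase volumes of a 4DCT): eight phases
train, one seeded-random phase validates, and the 70%-respiratory-phase
volume is held out as the test case. No cross-patient generalization is
claimed or tested.

The generative model has two stages:

1. **Coarse cycle stage** at half resolution. A reconstruction generator
   `GR` maps surface → volume, a verification generator `GV` maps volume →
   surface; both are encoder–transformer–decoder networks (early conv + two
   stride-2 convs with 32/64/128 filters, three residual blocks at 128
   filters, mirrored decoder with 64/32/16/1 filters, instance norm + ReLU,
   output Tanh rescaled to the normalized [0, 1] intensity range).
   Two Wasserstein critics `DR`, `DV` (four stride-2 k4 convs with
   64/128/256/512 filters, a shape-preserving k4 conv with 512 filters,
   global average pooling, linear head, no output nonlinearity) score the
   generated half-resolution volumes and surfaces.
2. **Refinement stage** at full resolution. The coarse reconstruction is
   trilinearly up-sampled and sharpened by an nnU-Net-style residual
   encoder–decoder: one residual conv block (RCB, 32 filters), five
   down-sampling RCBs (64/128/256/320/320), an anisotropic bottleneck RCB
   (stride 1×2×1, 320 filters), and a mirrored decoder (deconv k3×2×3
   s1×2×1 at the bottleneck, k2 s2 elsewhere) with concatenating encoder →
   decoder skip connections at matching scales, ending in a 1×1×1 conv with
   Tanh. At the full-scale 160×256×160 input the encoder feature chain is
   160×256×160 → 80×128×80 → 40×64×40 → 20×32×20 → 10×16×10 → 5×8×5 →
   5×4×5 and the decoder mirrors it back.

### Losses and schedule

Per epoch, three steps run over the training set:

- **Step 1** (generators, batch 2, half resolution):
  `L = Lsurf + Lvol + Ladv + Lidentity` with
  `Lsurf = ½·MAE(GV(Y), X) + ½·MAE(GV(GR(X)), X)`,
  `Lvol = ½·MAE(GR(X), Y) + ½·MAE(GR(GV(Y)), Y)`,
  `Ladv = (−DR(GR(X)) − DV(GV(Y))) / √N` (N = voxels per half-resolution
  grid; weight 1.0 on the normalized term, configurable), and
  `Lidentity = ½·MAE(GR(Y), Y) + ½·MAE(GV(X), X)`. The √N normalization
  puts the two objectives on a common per-voxel gradient scale: a
  ~1-Lipschitz critic has a unit-L2 input gradient (per-voxel influence
  ~N^(−1/2)) while a voxel-mean MAE contributes N^(−1) per voxel, so an
  unnormalized Wasserstein term dominates the supervised losses by a factor
  ~√N and the coarse stage never learns.
- **Step 2** (critics): `D(fake) − D(real) + λ·(‖∇_mix D(mix)‖₂ − 1)²`,
  λ = 10, with `mix = ε·fake + (1−ε)·real` and `ε ~ Beta(0.2, 0.2)` drawn
  per sample. The penalty differentiates the critic twice; the critics are
  therefore built exclusively from twice-differentiable primitives.
- **Step 3** (refiner, batch 1, reshuffled): `Lrefine = MAE(refiner(Ŷ⁰), Y)`
  where `Ŷ⁰` is the up-sampled coarse reconstruction recomputed from the
  current, frozen coarse stage in inference mode.

Adam optimizes all networks (initial lr 1e-4, betas (0.5, 0.999)); the lr
multiplies by 0.93 every 50 epochs. The validation refinement loss is
evaluated every 10 epochs and the parameter set minimizing it is the final
model. Inference runs normalize → downsample → `GR` → trilinear upsample →
refiner → un-normalize.

Two places in the objective are genuinely ambiguous in the source
formulation and are resolved as explicit design choices: the adversarial
term is the standard Wasserstein generator objective with unit weight, and
the identity loss uses the conventional `MAE(GR(Y), Y)` first term (a
config switch `identity_variant="as_printed"` selects the alternative
reading `MAE(GR(GR(X)), Y)`).

## Numerics: the autodiff layer

No deep-learning framework is part of this package's dependency set; the
trainable networks run on a purpose-built reverse-mode automatic
differentiation engine over numpy float32 arrays
(`surf2vol.autodiff`). Every primitive's vector-Jacobian product is itself
expressed in primitives, so gradients of gradients — required by the
gradient penalty — are exact rather than approximated; the three
convolution primitives (forward, adjoint, weight-gradient) are closed under
differentiation. Convolutions dispatch between direct numba kernels
(vectorized over the last spatial axis; used when output rows have ≥ 32
elements) and per-kernel-offset BLAS products (better for small feature
maps); the adjoint convolution is decomposed into stride³ sub-pixel
stride-1 correlations so no multiplications are spent on dilation zeros.
One deliberate asymmetry: generator and refiner instance-norm layers use a
fused first-order normalization primitive whose VJP is evaluated in closed
form (they are only ever differentiated once), while critics compose the
same normalization from primitives to stay twice-differentiable.

Weight initialization is zero-mean Gaussian (σ = 0.02), seeded per network;
instance norms are affine with learnable scale/shift; the generators' final
layer bias is initialized so their initial output equals the normalized
background (air) intensity rather than the Tanh midpoint 0.5, which would
start most voxels deep in the activation's saturated tail. With all conv
weights zero a residual block is exactly the identity map, which the tests
assert.

## Synthetic respiratory phantom

The clinical 4DCT cohort behind the method is not distributable, so the
package ships a parametric 4D phantom (`surf2vol.phantom`) whose defaults
define the study conditions used throughout the tests: a 40×64×40 grid at
(4, 3, 3) mm spacing holding a bumpy ellipsoidal soft-tissue body
(semi-axes 70/80/50 mm, ~40 HU, with a denser skin rind), two −800 HU
lungs, a 500 HU spine rod, three seeded soft-tissue blobs, and a 150 HU
tumor sphere (radius 10 mm) inside a lung. One cyclic respiratory driver
`cos(2π·phase)` moves the tumor along the superior–inferior axis with a
12 mm peak-to-peak amplitude **and** expands the chest wall by 5 mm, so the
body surface — additionally perturbed by a seeded smooth bump field (2 mm
RMS) that varies between patients — carries the information needed to infer
the internal state. Additive Gaussian noise (σ = 15 HU) emulates CT noise.
Per-patient anatomy (bumps, blobs, ±8% semi-axis jitter) is a deterministic
function of the patient seed.

What the phantom does *not* emulate: realistic organ shapes and HU
textures, hysteresis or irregular breathing, scatter/beam-hardening
artifacts, couch/clothing structures, or deformable (non-affine) inter-phase
anatomy changes beyond the modeled motion. Passing tests therefore
demonstrate that the pipeline can learn a surface→interior mapping when one
exists and that every computational step behaves as specified — not
clinical-grade image quality on real patients.

Surfaces are extracted by thresholding at −400 HU, 6-connected hole
filling, keeping the largest 6-connected component, and retaining the mask
voxels 6-adjacent to the exterior; the shell is one voxel thick and closed,
and re-extracting an extracted surface reproduces the same support.

## Preprocessing

Resampling is trilinear onto a grid covering the same physical extent
(full-scale default target 3×3×1.56 mm; the phantom is generated directly at
its target geometry so desk-scale runs skip resampling). Volumes are
centered on the body's center of mass by an integer-voxel shift computed
from the *surface* (so inference never needs the volume), then symmetrically
cropped/zero-padded (−1000 HU before normalization, its image afterwards) to
the fixed shape. Intensities are normalized to [0, 1] by the global min/max
of the **training split only**, stored in a `NormalizationRecord` and reused
at validation/test time; metrics are computed after inversion to HU.
Augmentation draws, with probability 0.5 per pair and epoch, one shared
shear → rotation → scale affine (magnitudes uniform in [0, 0.1], [0°, 10°],
[0, 0.1], random sign per axis), composed into a single matrix in physical
space and applied to both pair members with one trilinear resampling pass.

## Evaluation

MAE (HU), PSNR (dB) and SSIM are computed inside the body mask of the
ground-truth volume (interior + shell; exterior air excluded). PSNR uses
the dataset normalization range as its reference range and is capped at
200 dB for identical inputs. SSIM is volumetric with a 7³ uniform window
(C1 = (0.01·range)², C2 = (0.03·range)²), the local map averaged over
mask-centered windows. Cases are grouped by seeded k-means (k = 3, 10
restarts) on z-scored metric vectors, labels ordered by ascending group
MAE; t-SNE embeds the same standardized vectors for visualization only.

Surface curvature: the shell is filled, smoothed with a Gaussian (σ = 1.5
voxels) to suppress marching-cubes terracing, triangulated at the 0.5 level,
Taubin-smoothed (15 iterations), and the discrete mean curvature
(cotangent-Laplacian norm / 2 with barycentric areas) is evaluated per
vertex and averaged over 1-ring neighborhoods (5 passes). The summary is
COV = std/mean of curvature magnitudes; it is scale-free, ~0.09 for a
digitized radius-20 sphere (analytic value 0, residual from discretization),
and increases from sphere to ellipsoid to the bumpy phantom body. On this
operator the mean |H| of the digitized sphere reproduces the analytic 1/r
within a few percent, which anchors the discretization.

## Problem sizes and defaults

Full-scale defaults follow the published protocol (160×256×160 grid, 2000
epochs, batch 2 coarse / 1 refine, lr 1e-4 ×0.93 per 50 epochs, λ = 10,
Beta(0.2, 0.2)); training at that scale is a multi-hour GPU-class job and is
exercised here only through single forward-pass shape probes. The package's
quantitative experiments run at the desk scale codified in
`surf2vol.experiment.desk_scale_config`, chosen once for single-CPU
execution: 40×64×40 grids, network width 1/8 (the refiner automatically
reduces to three down-sampling stages at this shape), 150 epochs, 10 phases
per patient, one seed-pinned patient per run (~12 minutes on one CPU). The
optimizer protocol is the published one rescaled to those conditions: lr
width-compensated to 8e-4 and the ×0.93 decay time-compressed to every 4
epochs so the shortened run traverses the same number of decay steps.

The mean-training-volume baseline (voxel-wise mean of the eight training
phases) is the natural surface-blind reference: it is exactly right for
static anatomy and wrong only where respiration moves tissue. On this
phantom — whose anatomy is static apart from a 10 mm tumor and a 5 mm
chest-wall excursion, with σ = 15 HU noise — the baseline scores ≈ 21 HU,
essentially the noise floor (E|noise| ≈ 12 HU). The desk-scale model
reaches ≈ 67 HU / SSIM 0.82 on the held-out phase and does **not** beat
that baseline. A controlled upper-bound experiment (training the refiner
on an idealized coarse input, i.e. the up/down-sampled ground truth, for
the full 150-epoch budget) floors at ≈ 25 HU full-grid — above the
baseline — showing the gap is a joint consequence of the 1/8-width
capacity and the 13×-shortened schedule, not a defect of any single stage;
the same architecture at full scale and 2000 epochs is not bounded by this
result. Desk-scale training *does* demonstrate end-to-end learning: the coarse
cycle losses and the validation refinement loss both fall several-fold
over the run, and the reconstruction reproduces the body and organ layout
(SSIM 0.82 on the held-out phase).

## Known limitations

- The gradient-penalty critics dominate step-2 cost because double
  backprop through composed instance norms is graph-heavy; at desk scale
  this is acceptable, at full scale a GPU framework would be the right tool.
- `KMeans`/`TSNE` determinism is guaranteed per library version; pinned
  seeds make runs reproducible on one environment but not necessarily
  across sklearn versions.
- PSNR's reference range and SSIM's windowing are configurable because the
  field does not agree on a single convention; defaults are stated above
  and used consistently in all reported numbers.
- The phantom's surface–interior coupling is deliberately strong; with
  `breathing_amplitude=0` and `bump_amplitude=0` the task becomes nearly
  unidentifiable from the surface, which is scientifically expected and not
  a defect of the training code.
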