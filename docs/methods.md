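# Methods

`kneeshape` implements a neural shape model (NSM) pipeline for paired
anatomic surfaces — a femur-like bone and its articular cartilage — based on
signed distance functions (SDFs) and autodecoder training, together with the
downstream quantities that make such models clinically useful: surface
reconstruction error (ASSD), regional cartilage-thickness biomarkers, and
ordinal/binary disease staging from the learned latent space.

## Shape representation and conventions

A shape is a pair of watertight triangle meshes in one coordinate frame.
Signed distances are negative inside and positive outside; the inside test
uses the generalized winding number (threshold 0.5), which remains reliable
for thin closed shells such as cartilage where normal-based heuristics fail.
Before modeling, each bone is similarity-registered (rigid + isotropic
scale) to a reference shape, the transform is applied to the cartilage, the
pair is centered on the bone centroid, and both tissues are scaled by the
maximum radial distance so they lie inside the unit sphere.  Decoders are
queried over the enclosing cube [-1, 1]^3, which is also the marching-cubes
domain (resolution 256 at full scale; 64 in the desk-scale experiments, and
configurable throughout).

Registration is iterative closest point with scale: initialized by centroid
alignment and RMS-radius ratio, ten point-to-point (Umeyama) iterations for
robustness, then a linearized point-to-plane similarity update per iteration
for fast convergence, stopping on a 1e-7 relative misfit change (or a
perfect-fit floor) within a 100-iteration budget.  On noiseless copies this
recovers a planted similarity transform to machine precision.  Nearest-point
queries take the exact minimum over all triangles when the point x face
count is small and otherwise pre-filter with the 32 nearest triangle
centroids (a KD-tree), which is exact in practice on uniformly tessellated
meshes.

## Training-point sampling

Per surface, 500,000 points at full scale (15,000 in the desk-scale runs):
90% are surface points — drawn approximately blue-noise by batched
Poisson-disk dart throwing with radius sqrt(area/(n pi 0.7)), topped up with
area-weighted uniform samples if underfilled — perturbed by isotropic
Gaussian noise, half with sigma = 0.016 and half with sigma = 0.05
(normalized units); the remaining 10% are uniform over the cube.  The two
perturbed classes use floor(0.45 n) points each and the uniform class
absorbs the remainder, so the 45/45/10 split is exact.  Perturbed points are
clipped to the cube (this affects only the far tail of the sigma = 0.05
class).  Every point stores its signed distance to *both* surfaces, so each
minibatch supervises both decoder heads.  Minibatches contain equal numbers
of inside (s < 0) and outside (s >= 0) points — 17,000 at full scale, 1,024
in the desk-scale runs — drawn without replacement within each sign class.

## Decoders

All three decoders map (latent z, coordinate x) to two signed distances
(bone, cartilage), each through a final tanh scaled by the clamp bound
delta, so the output range matches the clamped regression target range
(delta = 1 for the hybrid, 0.1 for the implicit models).

**Hybrid (triplanar)** — z (length 512) passes through a linear dense layer
to 2048 features, reshaped to 2x2x512, then five stride-2 transpose
convolutions (kernel 4, padding 1; ReLU between layers, final layer linear)
to a 64x64x384 tensor split into three 64x64x128 planes (xy, xz, yz).  A
query point is projected onto each plane; corner-aligned bilinear
interpolation reads a 128-vector per plane and the three are summed into a
local latent, concatenated with x and decoded by a 3-layer width-512 ReLU
trunk with a linear 2-output head.  The dense expansion is deliberately
linear: autodecoder latents start near zero, and a ReLU there can saturate
dead and permanently sever the latent pathway, collapsing the model onto a
bias-encoded mean shape (we observed exactly this failure before making the
layer linear).

**Implicit MLP** — two independent 8-layer width-512 ReLU trunks (one per
tissue) on [x; z], with the 515-length input concatenated again into layer
4's input, and a scalar tanh head each.  Closed-form parameter count
4,733,954 (4.7 M at one printed decimal).

**Implicit MPA (modulated periodic activations)** — a sinusoidal
"synthesizer" trunk on x (frequency scale omega0 = 30 on the first layer)
gated elementwise, layer by layer, by a ReLU "modulator" trunk that takes z
(re-concatenated into every layer's input).  Modulator biases initialize at
1 so modulation starts near identity; with zero-mean initialization the
gates (magnitude well below 1) shrink the signal geometrically across the 8
layers and the latent gradient vanishes at init.  Sinusoidal weights use the
standard uniform ranges (1/fan_in for the first layer, sqrt(6/fan_in) for
hidden layers).

Kernel size for the transpose convolutions is a design choice (the standard
exact-doubling kernel 4 / stride 2 / padding 1); with it the hybrid model
counts ~21.6 M parameters and the MPA ~5.8 M.  The desk-scale ("tiny")
variants shrink the latent to 32, planes to 16x16x32 (3 deconv layers, 48
channels), and the trunk to width 128.

All neural components run on a compact reverse-mode autodiff core written on
numpy (float32), implementing exactly the operations the decoders need —
matmul, broadcast arithmetic, ReLU/tanh/sine/sigmoid, strided 2-D transpose
convolution, bilinear plane reads with scatter-add backward — plus AdamW
with decoupled weight decay and per-group learning rates.  Every op is
gradient-checked against finite differences in the test suite.

## Autodecoder training

Each training shape owns a latent code initialized N(0, 0.01^2); codes and
decoder weights are optimized jointly by AdamW (weight decay 1e-4 on network
weights only — the latents are regularized explicitly).  Per epoch the
shapes are visited in shuffled order with one optimizer step per shape; a
step draws one balanced batch from the bone set and one from the cartilage
set and sums the reconstruction loss over all four (batch x head)
combinations plus the weighted latent penalty.

The reconstruction loss is a curriculum-weighted clamped L1:
mean of w |clamp(s_pred, +-delta) - clamp(s_true, +-delta)| with
w = 1 + lambda sign(s_true) sign(s_true - s_pred), which up-weights
wrong-sign ("hard") predictions by 1 + lambda and down-weights easy ones by
1 - lambda; lambda = 0 is plain clamped L1.  lambda ramps exponentially from
0 to 0.2 — we use the normalized convex ramp
lambda_max (e^{5 e/E} - 1)/(e^5 - 1) over the first 90% of epochs (1800 of
2000 at full scale).  The latent penalty sum_i z_i^2 / sigma^2 (sigma = 100)
is weighted by a linear warmup (first 5% of epochs) times a cyclic anneal
beta(t) = 2t/T for t < T/2 and 1 otherwise, with 5 cycles over the run.
Learning rates decay as lr0 f^{e/i} with a continuous exponent; full-scale
presets are (5e-3, 1/1.05, 16.67) for the network and (1e-4, 0.1, 1000) for
the latents.

**Desk-scale schedule.** The scaled 300-epoch study keeps the initial
learning rates but decays more gently — network i = epochs/60 (~18x total
decay) and latent lr0 = 1e-3 with a 10x decay over the run.  With 10 shapes
each latent receives only ~300 updates (versus thousands of epochs at
population scale), and the full-scale latent schedule leaves the codes at
their initialization, i.e. an uninformative latent space; raising the latent
rate is the scaled counterpart of giving the codes a comparable total
learning budget.

## Test-time reconstruction

To encode a new pair with frozen weights: decode z = 0 and extract the
model-mean bone; similarity-register the input bone to it (carrying the
cartilage along; on registration failure, fall back to centroid/scale
alignment with a warning); rescale into the unit sphere; sample 20,000
surface points per surface once (2,000 desk-scale; target s = 0) and
optimize a randomly initialized latent (N(0, 0.01^2), or a warm start) by
clamped L1 with Adam, lr decayed 0.9 every 20 epochs, early stopping with
patience 50, best latent restored.  No latent regularization is used.  The
initial fitting rate is 5e-3 (unspecified upstream; the same magnitude as
network training).  The clamp during fitting defaults to |s| = 0.1; the
desk-scale hybrid experiments use the decoder-matched bound delta = 1, since
with a freshly initialized tiny model the 0.1 clamp zeroes gradients for
most points and stalls the fit.  Surfaces are extracted by marching cubes on
a [-1, 1]^3 grid per head and mapped back through the inverse similarity
transform.  A head whose grid never changes sign yields no surface for that
tissue — reported, not raised, since degenerate latents are a legitimate
outcome.

## Cartilage thickness biomarkers

Thickness at a bone vertex is measured by casting a ray along the outward
vertex normal (area-weighted fallback for degenerate normals) through the
closed cartilage mesh (vectorized Moller-Trumbore).  Rays start 0.05 mm
inside the bone so shells whose inner wall coincides with the bone surface
are entered cleanly; hits closer than 1e-5 length units are merged (a ray
through a shared mesh vertex hits every incident triangle).  With an even
number (>= 2) of intersections within 10 mm, thickness is the distance
between the first two; otherwise 0.  On constructed constant shells the
interior of the cap is recovered to ~0.1%; rim vertices are only partially
covered and are excluded from recovery statistics via a 1-ring interior
mask.

Five anatomic subregions (trochlea, medial/lateral central, medial/lateral
posterior) — and the six-region variant that splits the anterior band —
are defined analytically on canonically posed shapes by angular sectors: arc
position psi = atan2(-z, y) along the anterior-to-posterior wrap, and the
medial/lateral side by the sign of x.  Real meshes in arbitrary pose must
supply per-vertex labels; reproducing template-based anatomic atlases is out
of scope.  Regional biomarkers are arithmetic means over each region's
vertices *including* zero-thickness vertices (configurable), so
full-thickness holes lower the regional mean.  Reconstruction fidelity of
the biomarkers is summarized per region by RMSE and by the population
standard deviation of the differences (SDD), which removes systematic bias;
RMSE^2 = bias^2 + SDD^2 holds by construction.

## Clinical heads

Labels follow standard knee-OA scoring: KL grade 0-4 with OA = KL >= 2;
MOAKS osteophyte grades binned 0-2 (2 and 3 merge); cartilage thinning
binarized at the >10%-of-region level (raw grades 2/3 positive); cartilage
holes binarized at any grade >= 1.  Predictors operate on latent codes: a
grid-searched MLP (depths {2,3}, widths {64,128,256}, dropout {0.2,0.4},
learning rates {1e-3,1e-4,1e-5}, batch {64,128,256,512}) and logistic
regression.  Binary tasks use binary cross-entropy; graded tasks use a
consistent-rank-logits (CORAL) head — one shared weight vector with K-1
ordered biases, trained with cumulative-target BCE, predicting the count of
thresholds whose sigmoid exceeds 0.5.  Winners are selected on a validation
split by quadratic-weighted kappa (ordinal), AUROC (balanced binary) or
AUPRC (imbalanced); decision thresholds default to validation-tuned
(test-set tuning exists only behind an explicit flag, for parity with
protocols that report it).  Interpretability utilities provide linear latent
interpolation between class-mean codes and traversal along a logistic
classifier's unit coefficient vector, whose predicted probability is
strictly monotone along that direction by construction.

## Synthetic data

The generator is the package's study population: femur-like, not a femur.
Bone = icosphere-topology ellipsoid (radii ~ N((30, 36, 33), 1.5^2) mm) with
a low-order smooth radial deformation (5 fixed quadratic direction basis
functions, coefficients ~ N(0, 0.02^2)), in a fixed canonical pose (+x
medial, +y anterior, +z proximal).  Cartilage is a closed shell over the
atlas band: inner wall on the bone, outer wall radially offset by the
thickness field (base 2.2 mm plus a smooth +-0.35 mm variation), rim
stitched; holes floor the offset at 0.02 mm to keep the mesh manifold.
Disease severity per sample is a scalar in [0, 1] (stratified across the
population so 30 samples span all label classes); per region it drives
MOAKS-style raw grades via fixed thresholds on a noisy severity score.
Osteophytes are Gaussian radial bumps (amplitudes 1/2/3 mm for raw grades
1/2/3, angular width 0.25 rad) at the cartilage rim of the affected region;
thinning halves the thickness over a patch sized by bisection-free quantile
matching to a grade-specific area fraction (grade 1: 3-8%, grade 2: 16-30%,
grade 3: 35-55% — straddling the 10% binarization threshold with a safety
gap); holes zero the thickness over a 0.22 rad footprint.  The KL-like
composite is a fixed clipped function of total feature burden (osteophyte
binned sum + 2x thinning binaries + 2x hole binaries, thresholds 0/4/10/18)
— it exists to exercise ordinal machinery, not to be biologically faithful.
Future-event labels are severity-linked Bernoulli draws.

What the generator does *not* emulate: real femoral geometry and its
population covariance, segmentation noise, pose variability, imaging
artifacts, and realistic label noise or prevalence.  Passing tests therefore
demonstrate correctness of the pipeline's mechanics and internal
consistency, not clinical performance on MRI-derived shapes.

## Problem sizes and numerical choices

The test suite and the acceptance script run the same desk-scale
configuration, chosen once: 10 training shapes (2 held out), icosphere
subdivision 3 (642 vertices), 15,000 samples per surface, tiny hybrid
decoder, 300 epochs, batches of 1,024 points, reconstruction grid 64 —
sized so a fresh, single-CPU run finishes comfortably while still
exhibiting the pipeline's qualitative behavior (loss collapse, latents that
beat the mean shape on every training shape, refits within two grid
spacings).  Winding numbers use a numba-compiled kernel when numba is
importable and a chunked numpy path otherwise.  Degenerate inputs raise
typed errors (non-watertight meshes report their open-edge count; empty
level sets raise EmptySurface; single-sign batches warn and resample with
replacement).  All randomness flows from explicit integer seeds;
training, sampling, fitting and generation are bit-reproducible given the
seed.

## What the desk-scale latent space does and does not resolve

Latents fitted (frozen weights) to a held-out 36-shape cohort are evaluated
by pooled 3-fold cross-validated logistic regression.  At the 10-shape
training scale the latent space linearly separates OA status and severe
osteophytes above their prevalence baselines, but *not* full-thickness
cartilage holes — their footprints are small relative to what a tiny model
trained on 10 anchors encodes.  Hole prediction is therefore not asserted in
the tests; population-scale training is expected to recover it, but that is
outside what this package's experiments can demonstrate.

## Known limitations

* The five/six-region atlas is analytic and only valid in the generator's
  canonical pose; real data need external label files.
* The candidate-prefiltered nearest-triangle query is exact only up to the
  32-candidate heuristic (irrelevant for uniform tessellations; the exact
  path covers all small meshes).
* The MPA decoder's published parameter count is not reproducible from its
  stated architecture; our count follows the architecture as described.
* Desk-scale training quality is limited by the tiny model and short
  schedule; reported reconstruction errors are not comparable to
  population-scale results.
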