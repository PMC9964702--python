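# Methods

`sdsseg` implements hierarchical brain-tumor-region segmentation with a
hybrid 2D/3D multi-scale attention network trained by selective deep
supervision (SDS), together with everything needed to exercise it at
desk scale: a synthetic phantom generator, the preprocessing chain,
volumetric evaluation metrics, and a seeded training harness.

## The segmentation problem

BraTS-style scans are multi-modality MRI volumes (FLAIR, T1, T1ce, T2)
with voxel labels 0 (background/healthy), 1 (necrotic/non-enhancing
core), 2 (peritumoral edema) and 4 (GD-enhancing tumor).  Evaluation
uses three nested regions:

    WT (whole tumor)     = {1, 2, 4}
    TC (tumor core)      = {1, 4}
    ET (enhancing tumor) = {4}

so ET ⊆ TC ⊆ WT always holds for reference labels.  The nesting is the
lever the training scheme exploits.

## Network

Two encoders run in parallel on each axial slice *n*:

* a **3D encoder** over the five-slice context patch (slices n−2 … n+2,
  edge-replicated at the stack ends), built from bottleneck residual
  blocks (1×1×1, 3×3×3, 1×1×1 convolutions; in-plane stride 2 on the
  downsampling block, slice axis untouched; output channels 4× the
  bottleneck width);
* a **2D encoder** over slice *n*, built from blocks of two
  (conv 3×3 → ReLU → batch-norm) stages followed by 2×2 max-pooling.

After each of the four levels a **bridge block** (1×1×1 conv → ReLU →
BN, max-pool over the full slice axis, reshape dropping that axis)
turns the 3D features into a 2D map that is concatenated with the 2D
encoder's output; the concatenation feeds the next 2D block.

The decoder upsamples through three **DeConv blocks** (nearest 2×
upsample, concatenate the skip, two conv→ReLU→BN stages).  Each skip is
filtered by an **additive attention gate**

    α = σ( ψᵀ ReLU(W_x x + W_g g + b_g) + b_ψ ),   x̂ = α · x

with all linear maps channel-wise 1×1 convolutions and one scalar α per
pixel.  The gating signal g comes from one level coarser (the
bottleneck for the first gate, the previous decoder output afterwards)
and is upsampled 2× before W_g.  α is clipped to [1e-6, 1−1e-6]: the
sigmoid saturates to exactly 0/1 in float32, and the gate's contract is
that no pixel is ever fully killed or fully passed.

Four heads emit full-resolution per-pixel probability maps: three
auxiliary heads lift the intermediate decoder levels to full size with
stride-2 transposed convolutions and a 1×1 projection + softmax; the
final head applies one transposed-convolution upsampling and a 1×1
projection + softmax to the last decoder level.  Only the final head
drives predictions.

Channel widths double per level from `base_channels` (desk scale 16,
reference scale 64); widths are an open choice, since only the block
structure is fixed.  Batch normalization is placed *after* ReLU,
following the block descriptions this architecture comes from, rather
than the more common reverse order.  Weights are He-uniform; every
block draws from its own seeded stream so the shared trunk's
initialization is identical across head configurations — this is what
makes "same random weights" comparisons between supervision schemes
exact.

## Selective deep supervision

WT/TC/ET overlap, so a softmax over the raw regions would be ill-posed.
Each head's region subset is converted into mutually exclusive classes
by hierarchical set difference:

    {WT}          → (background, WT)                      2 classes
    {WT, ET}      → (background, WT∖ET, ET)               3 classes
    {WT, TC, ET}  → (background, WT∖TC, TC∖ET, ET)        4 classes

The default scheme supervises the earliest decoder head with {WT}, the
next with {WT, ET}, and the last two outputs with all three regions.
Losses are per-pixel negative log-likelihoods (mean reduction by
default; probabilities clamped at 1e-12 before the log).  The total
objective is

    L = L_main + Σ_d η_d·γ^epoch · L_d + λ·(‖W‖² + Σ_d ‖ŵ_d‖²)

with defaults η = (0.4, 0.3, 0.2), γ = 0.95 per epoch, λ = 1e-4.  The
balancing weights and their decay are implementation choices (only the
decay's existence is prescribed by the method); they are configuration
keys.  Terms with zero coefficient are skipped entirely, which makes
two reductions exact rather than approximate: η ≡ 0 reproduces
conventional training step for step, and the all-region scheme with
γ = 1 reproduces standard deep supervision step for step.

## Preprocessing

Per volume: (1) drop blank slices ("blank" = no voxel above 0 in any
modality) from both ends of the stack only; (2) crop each slice to a
fixed window (default 160×160, desk 56×56) centered on the in-plane
content bounding box, clamped to the volume and zero-padded if the
volume is smaller; (3) histogram-equalize the foreground of each
modality by the cumulative-histogram map over 256 bins onto the
modality's dynamic range, leaving background untouched so air does not
dominate the CDF; (4) min-max normalize each modality to [−1, 1]
(constant channels map to 0 with a warning).  Slices are then resized
bilinearly (labels nearest-neighbour) to the network input size
(default 224×224, desk 64×64); cropping to one printed size and
resizing to the other keeps both as independent configuration keys.
Every geometric step records a `CropRecord`, and the inversion
re-embeds predictions into the original volume with zero label loss
(tested exactly).

The five-slice context patch is canonical; a three-slice variant is
available through `context_halfwidth=1`.

## Phantoms

A phantom is a brain ellipsoid of elevated intensity in a zero
background containing three nested tumor ellipsoids (edema, core,
enhancing).  Nesting is guaranteed geometrically: a child ellipsoid
scaled by s from its parent may have its center jittered by at most
0.9·(1−s) in the parent's normalized coordinates.  Per-region,
per-modality mean intensities default to a qualitative mimic of real
contrast (edema bright on FLAIR/T2, enhancing bright on T1ce, core
dark on T1) with i.i.d. Gaussian noise, σ = 0.04 against between-region
gaps ≥ 0.2, so regions are statistically separable but not trivially.
Identical spec + seed is bit-identical.

What phantoms do **not** emulate: anatomy, texture, bias fields, Rician
noise, multi-focal or non-ellipsoidal tumors, inter-rater label noise.
Passing tests therefore demonstrate that the architecture, losses,
training loop and geometry handling are correct and that the method
learns nested-region segmentation end to end — not that it reaches any
particular accuracy on real scans.

## Training

Stochastic gradient descent (optional classical momentum, default 0 as
in the reference setup; the desk profile uses momentum 0.9 with
lr 0.05 so short schedules converge), batch 8, early stopping on
validation loss with patience 10 (desk experiments use smaller caps).
The split is by volume, never by slice.  All randomness — weights,
split, per-epoch shuffling — derives from the configured seed;
identical configuration reproduces the history bit for bit on one
thread.

The numerical substrate is a small reverse-mode autodiff engine on
numpy arrays written for this package (float32 tensors; convolutions
evaluated as one GEMM per kernel offset on a channels-last layout).
Every operation's gradient is verified against central finite
differences in the test suite.

## Evaluation

Overlap measures are exact voxel counting: Dice 2|P∩R|/(|P|+|R|)
(the literal printed form of the Dice formula in the source evaluation
protocol uses |P∪R| in the denominator, which contradicts its stated
[0,1] range; the standard denominator is implemented); sensitivity
|P∩R|/|R|; and a prediction-conditioned "specificity" |P∩R|/|P| —
precision — implemented exactly as the protocol prints it, with the
conventional true-negative rate available separately.  Hausdorff
distances are computed between 6-connectivity boundary surfaces with
physical voxel spacing (unit recorded in the report); HD95 takes the
95th percentile (linear interpolation) of each direction's
nearest-neighbour distances, then the max of the two directions.
Conventions for degenerate inputs: both masks empty → Dice 1;
sensitivity/specificity/HD undefined on the relevant empty mask →
NaN with a warning.  All measures are tested for exact agreement with
brute-force counting and all-pairs distance oracles on random masks.

## Desk-scale experiment sizes

Chosen once as the package's study conditions:

* **Learning smoke test** — 30 zero-noise phantoms of 16×64×64 voxels,
  desk network (base 16, 64×64 inputs), SDS, ≤ 300 SGD steps: reaches
  held-out whole-tumor Dice ≈ 0.99 and near-zero training loss.
* **Scheme comparison** — 12 noisy phantoms of 12×32×32 voxels, base
  width 8, 32×32 inputs, lr 0.05 with momentum, up to 20 epochs with
  early-stopping patience 4, five seeds with shared initialization per
  scheme.  This trains each scheme to (near-)convergence, which is the
  regime in which the original comparison is defined; mid-run snapshots
  at this scale are dominated by seed noise.  The train–validation gap
  is summarized as the mean over epochs of (validation − training) main
  loss, i.e. the average separation of the two learning curves.

## Known limitations

* The 3D output path is slice-wise; no volumetric decoding.
* Full-scale (224×224, base 64, 600 epochs) training is recorded as the
  `paper` profile but is far outside desk runtime.
* The attention gate's F_int and per-level widths are defaults, not
  reproductions of unpublished values.
* Hausdorff distances on surfaces differ from full-mask point-set
  distances for strictly nested masks; the surface convention (the one
  standard in BraTS tooling) is used throughout.
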