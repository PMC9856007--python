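# Methods

`axialseg` implements a 3-D encoder–decoder segmentation network whose skip
connections are fused by a factorised axial attention mechanism, trained with
a deep-supervised hybrid Dice + binary-cross-entropy loss, together with the
surrounding pipeline: BraTS-convention I/O, preprocessing, augmentation,
metrics, a training/inference engine, and a synthetic phantom generator that
makes the whole stack exercisable offline on CPU.

## Problem setting

Gliomas are annotated in multi-institutional MRI (the BraTS convention) as
three tissue classes on four co-registered 1 mm isotropic modalities
(T1, T1c, T2, FLAIR): label 1 necrotic/non-enhancing core, label 2
peritumoral edema, label 4 GD-enhancing tumor. Evaluation uses three nested
regions — enhancing tumor ET = {4}, tumor core TC = {1,4}, whole tumor
WT = {1,2,4} — so the network predicts three *independent* sigmoid channels
(multi-label, not softmax-exclusive). Predictions are decoded back to labels
innermost-first (ET > TC > WT) so that an inconsistent voxel keeps its most
clinically critical call.

## Network

A six-resolution-level U-shape. Each level holds a basic block of two 3×3×3
convolutions with LeakyReLU (slope 0.01); stride-2 convolutions halve
resolution and perform the channel increase; transposed convolutions
(kernel 2, stride 2) restore it. Filters double from 32 up to a cap of 320,
so a 128³ patch yields per-level extents 128…4 and channels
32, 64, 128, 256, 320, 320. The final 1×1×1 convolution maps to 3 sigmoid
channels. Instance normalisation follows every convolution by default —
batch size 2 makes batch statistics useless and training at this depth is
fragile without any normalisation — and can be disabled
(`NetworkConfig.instance_norm=False`).

### Axial attention fusion

Full 3-D self-attention over D×H×W voxels needs a (DHW)² attention matrix;
factorising it by axis needs D²+H²+W² entries per line batch
(`attention_matrix_elements` computes both). At each attention-bearing skip
level the block receives the skip feature F_sc and the coarser decoder
feature F_pre, and computes

    F      = ConvTranspose(F_pre)            # doubled extents, skip channels
    F_saD  = AttD(F + posD)                  # attention along depth lines
    F_saDH = AttH(F_saD + posH)              # then height
    F_saDHW= AttW(F_saDH + posW)             # then width
    F_att  = F_saDHW + F
    F_out  = F_att + F_sc

Per axis, q(f) = F W_q and k(f) = F W_k project to a reduced dimension
Ĉ = heads × head_dim, v(f) = F W_v keeps all C channels (partitioned across
heads), the correlation δ_{j,i} = q(f_i)ᵀk(f_j) is a plain inner product —
no 1/√d temperature — rows are softmax-normalised, the weighted values are
summed, and a final linear map restores the channel space. Head counts and
head dimensions start at (4, 16) at the shallowest attention level and
double at each coarser one.

Placement: attention cannot be afforded at the full-resolution skip, and in
a six-level U-shape exactly four sub-full-resolution skip connections exist
(levels 1–4); all four carry attention by default. The bottleneck has no
skip and hence no fusion block. Both the level set and the axis order are
configuration-exposed for ablation, as is the F_saDHW + F residual
(`aam_residual`) and whether each axis attention gets its own position
embedding (`aam_embed_per_axis`, default) or only the first one does.

Position embeddings are learned additive per-axis vectors (one C-vector per
position). Non-attention skip levels fuse by concatenation followed by the
decoder block — at attention levels the block's own +F_sc addition already
performs the fusion, so its output feeds the decoder block directly.

### Deep supervision

Auxiliary 1×1×1-conv sigmoid heads sit at the middle three decoder levels
(1/2, 1/4, 1/8 resolution). Each auxiliary output is upsampled to full
resolution (nearest-neighbour repetition; its exact adjoint, sum-pooling,
makes the backward pass cheap) and scored by the same loss as the main head,
with weights halving per level:

    L_total = L_H1 + 0.5 L_H2 + 0.25 L_H3 + 0.125 L_H4

## Loss

    L_Dice = 1 − (2 Σ y_p y_t + ε) / (Σ y_p + Σ y_t + ε),   ε = 1e-5
    L_BCE  = mean(−λ y_t log y_p − (1−y_t) log(1−y_p)),      λ = 1

The Dice sums pool batch, channels and voxels into one virtual sample
("batch Dice"): per-sample Dice has an exploding gradient whenever a sample
contains no tumor, while the pooled denominator stays large as long as any
sample in the batch does. ε in numerator and denominator makes the perfect
and the both-empty cases well defined. Predictions are clipped to
(1e-7, 1−1e-7) inside the BCE. λ defaults to 1 and is configurable.

## Training

Adam (β₁ = 0.9, β₂ = 0.999), initial learning rate 1e-4 decayed as
lr(e) = lr₀ (1 − e/E)^0.9, batch size 2, 250 mini-batches per epoch for
E = 300 epochs, five-fold cross-validation with random equal-size splits.
Each batch element is a training case sampled with replacement, passed
through the augmentation pipeline. All randomness — splits, initialisation,
sampling, augmentation — flows from one root seed through named substreams,
so runs are bit-reproducible.

Preprocessing per case: crop to the minimal bounding box of nonzero
intensity across channels; per-channel z-score, computed over nonzero voxels
only when the crop shrank the voxel count by more than one quarter
(cropped/original < 3/4 — the sentence defining this rule is ambiguous, so
the mode is also directly settable); center-crop / zero-pad to the patch
size, with the inverse map retained. Statistics are per channel per case,
the standard choice for multi-modal MRI.

Augmentation applies five transforms, each independently with probability
0.3: rotation (±15° per axis), scaling (uniform factors in (0.65, 1.6),
independently per axis by default — the alternative single shared factor is
the `scale_per_axis=False` branch), elastic deformation (smoothed
displacement field, σ = 8 voxels, amplitude 3 voxels), gamma on the
min–max-normalised range (0.7–1.5), and multiplicative brightness (0.7–1.3).
Magnitudes other than the scaling range follow common 3-D segmentation
practice and are config-exposed; they are declared defaults, not reverse-
engineered values. Spatial transforms resample intensities trilinearly and
masks by nearest neighbour (which preserves binarity and the ET ⊆ TC ⊆ WT
nesting); out-of-field voxels become 0.

Whole-volume inference tiles the preprocessed volume with patch-sized
windows at 50 % overlap and blends sigmoid outputs under a Gaussian window
weight (σ = patch/8); a strict single-center-window mode is available.
Channels are thresholded at 0.5 before decoding.

## Tensor backend

No GPU framework is assumed: `axialseg.grad` is a compact tape-based
reverse-mode autodiff over float32 numpy arrays, with exactly the primitives
the model needs. 3-D convolution runs as im2col + GEMM; its input gradient
is the correlation of the zero-stuffed output gradient with the
channel-swapped flipped kernel, and its weight gradient reuses the forward's
column matrix. Transposed 2× convolution is a channel contraction plus an
interleaving reshape (blocks do not overlap). Instance normalisation is a
fused primitive with a hand-derived backward. Every primitive is checked
against central finite differences in the test suite, and the fused
instance norm against its composite-op expansion.

## Synthetic phantoms

The generator emulates the *statistical structure* of skull-stripped
multi-modality cases, not their appearance: an ellipsoidal head of nonzero
intensity on an exactly-zero background; inside it, randomly placed,
randomly rotated, per-axis anisotropic nested tumor ellipsoids — edema shell
(2) around core shell (1) around enhancing centre (4) with radius fractions
0.4 / 0.7 / 1 of the outer radius; four channels that share geometry but
differ by a tissue-contrast table (enhancing brightest on the T1c-like
channel, edema brightest on the FLAIR-like channel); Gaussian noise
(σ = 5 intensity units against tissue contrasts of order 10–70) inside the
head only. Tumors occupy well under 10 % of the volume, reproducing the
class imbalance that motivates the batch Dice. Default grid 160×160×112 at
1 mm; the desk-scale configuration used by the tests and the acceptance
script (`small_phantom_config`) is a 48³ grid whose cropped head fits a 32³
patch, with proportionally larger tumors so subregion statistics remain
meaningful.

What the phantoms deliberately lack: MRI texture, bias fields, partial-
volume gradation, multi-site intensity variation, and anatomically shaped
lesions. Passing the phantom-based tests therefore demonstrates that the
architecture, losses, metrics and engine are implemented correctly and that
the network can fit and generalise within this family — not that it reaches
any particular accuracy on real MRI.

## Scaled-down study sizes

CPU-scale runs use `tiny_train_config`: patch 32³, 4 levels, 8 base filters
(cap 64), attention at both sub-full-resolution skip levels, two auxiliary
heads (weights 0.5, 0.25), 10 epochs × 25 iterations, lr₀ = 1e-3 — the
higher rate compensating for the short optimisation, with the full-scale
default left at 1e-4. The learning experiment trains on 16 phantoms and
evaluates on 4 held-out ones through the full sliding-window path.

## Degenerate inputs and conventions

* All-zero volume: bounding-box extraction raises (`EmptyVolumeError`).
* Zero-variance channel: z-score raises, naming the channel.
* Dice of two empty masks: 1.0 (configurable).
* Hausdorff with an empty surface: NaN by default, or a caller-chosen
  worst-case constant. HD95 is the 95th percentile of directed
  nearest-neighbour surface distances, maximised over the two directions;
  surfaces are face-connected erosion residues; distances are in voxel units
  unless a spacing is supplied.
* Sensitivity with empty reference: NaN.
* z-score is intentionally not idempotent (nonzero-mode statistics change
  after the first application); no such claim is made.

## Known limitations

* CPU-only: full-scale 128³ training is out of reach; the default
  configuration is validated structurally (schedule, shapes, parameter
  wiring) and exercised end to end only at reduced scale.
* Single-label-set support ({0,1,2,4}); no DICOM, registration or
  skull-stripping — inputs are assumed preprocessed as BraTS distributes
  them.
* The enhancing-tumor channel is the slowest to converge in the scaled-down
  regime (smallest structure); the acceptance report includes its held-out
  Dice alongside TC/WT rather than hiding it.
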