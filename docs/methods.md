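# Methods

This note documents the models and procedures implemented in `deepmir`,
the assumptions behind them, and the design decisions taken where the
protocol left choices open.

## Segmentation model

The core model is a 2D U-Net operating on axial slices. The default
("6-resolution") variant has five analysis stages — each two 3×3
padded convolutions with stride 1, each followed by batch normalization
and ReLU, closed by 2×2 max pooling — a central block of the same two-conv
form, and five synthesis stages: a 2×2 stride-2 transpose convolution
doubling the spatial size, concatenation with the equal-sized analysis
feature map, and two further conv-BN-ReLU layers. With padded convolutions
the spatial size is preserved within each resolution, so a 256×256 input
yields a 256×256 output and the central block sees an 8×8 map. The sixth
resolution (relative to the classic five-resolution U-Net) is what gives
the receptive field and capacity to resolve lesions of only a few voxels.

Heads:

* single-class — 1×1 convolution to one channel, sigmoid; a voxel is
  accepted when its probability is ≥ 0.5;
* multiclass — 1×1 convolution to `n_classes` channels, ReLU, then
  softmax; voxels take the argmax class. The ReLU before the softmax is
  unusual (it zeroes negative logits and therefore flattens part of the
  probability simplex) but is the specified head; `relu_before_softmax=False`
  selects a plain softmax head for ablation.

Training minimizes mean cross-entropy (binary or categorical) over pixels.

**Feature widths** are not part of the published architecture; the package
defaults to the classic 64-channel base doubling per stage (capped at
1024), fully configurable — the desk-scale runs use `base_width=8`.

**Head bias initialization.** Lesion voxels are a ~10⁻³ fraction of each
slice. With a neutral head, short training runs can collapse into the
confident all-background solution and stay there, because the loss is then
already near its floor and the residual gradient from a handful of lesion
pixels is too weak to escape within the epoch budget. The head bias is
therefore initialized *in favour of the lesion classes* (+2 logits for the
sigmoid head; −2 on the background logit for the softmax head): the
network starts over-segmenting and must learn discriminative features in
order to push background down, which it does quickly, while lesion pixels
retain positive logits. This is an initialization choice only; the loss
and architecture are unchanged, and `head_bias_init=0` restores the
neutral start.

**Baselines.** The 5-resolution variant (16×16 central map at 256×256) and
the original unpadded U-Net are provided for comparison. For unpadded
("valid") convolutions every conv pair shrinks the map by 4 and skip
feature maps are center-cropped before concatenation; the closed-form size
recurrence reproduces the classic 572 → 388 shrinkage and is validated by
a real forward pass at 188 → 4. Labels must be center-cropped to the
output size when training this baseline.

**Numerical backend.** The layers (im2col convolution, batch
normalization, 2×2 max pooling with single-winner gradient routing, 2×2
stride-2 transpose convolution, fused sigmoid-BCE and softmax-CE losses,
Adam) are implemented in numpy. The backward pass of each layer and of the
assembled network is checked against central finite differences in float64
in the test suite. Parameters are float32 in normal use.

## Preprocessing

Each modality volume is z-normalized to zero mean and unit variance *per
3D volume* (not per slice — slice-wise scaling would distort lesion
contrast between slices of one brain). QSM is first truncated to ±kσ with
k = 5, σ taken over the full grid: QSM reconstructions carry
high-intensity noise concentrated at the brain boundary, and without
truncation those spikes dominate the normalization and compress the
contrast of everything else. Whether σ should be computed within a brain
mask is unknown; the full-grid convention is the default and a mask option
exists. Volumes are sliced along the axial (last, configurable) axis and
edge-padded to a square target (256 default; the desk-scale phantom runs
use 32). Padding replicates edge values for images and uses background for
labels, split symmetrically with the extra voxel on the high side; inputs
larger than the target are center-cropped. The padding geometry is
recorded per slice so that per-slice predictions can be stacked back into
the original volume exactly.

## Augmentation and class balancing

Lesion-bearing axial slices are rare, so augmentation is selective: every
slice containing a label of interest is augmented with the full policy,
then randomly chosen lesion-free slices are augmented identically until
the two groups are of similar size (they end within one slice's
augmentation yield of each other). The policy is: integer translations
drawn from [−45, 45] per axis (applied as (tx, ty) pairs; "per axis"
counts are read as paired draws), rotations by integer degrees d drawn
from [1, 60] and applied as both +d and −d, and left–right mirroring.
Multiclass experiments use 10 translation pairs and 16 rotation angles per
slice; single-class counts are unstated in the protocol and default to
half (5 and 8), preserving the stated ordering that multiclass training
uses more augmentation. Images are interpolated linearly with edge fill;
labels use nearest-neighbour with background fill so class values stay
integral. Both training and validation sets are augmented (a flag disables
validation augmentation for ablation). The ±45 range is calibrated for
256×256 slices; desk-scale 32×32 runs scale it to ±8 so that the brain
stays in frame.

## Cross-validation and model selection

Evaluation uses participant-level leave-one-out cross-validation: each
fold holds one participant out and randomly splits the rest into training
(75%) and validation (25%) — 17/6 for a 24-participant cohort, with the
count rule `round(0.25·(n−1))`. The split is re-randomized per fold with
seeded generators. Training runs for at most `max_epochs` (30 by default);
after every epoch the validation IoU is computed (pooled over pixels for
single-class tasks; mean over lesion classes present in the reference for
multiclass) and the weights of the maximum-IoU epoch are retained, ties
resolving to the earlier epoch. The retained model predicts the held-out
participant, so n participants are predicted by n distinct models with no
leakage. Optimizer settings (Adam, lr 10⁻⁴ default, batch 16) are not part
of the published protocol and are configuration; the desk-scale runs use
lr 10⁻², batch 8, and a cap on training samples drawn per epoch to bound
runtime.

## SWI composition

SWI is composed per slice from one echo's magnitude and raw phase. The
homodyne high-pass filter divides the complex image m·e^{iφ} by its
low-pass version, obtained by windowing central k-space with a 64×64
window; the filtered phase is the phase of that ratio. The negative phase
mask is Haacke's linear form — (π + φ)/π for −π < φ < 0, else 1 — raised
to power 4 and multiplied with the magnitude. The k-space window's taper
is unstated; a Hann taper is the default (a raw rectangular window rings)
and the rectangular variant is retained. The window is built from the
frequency distance to DC so it is exactly Hermitian-symmetric: real images
have real low-passes, and a zero-phase input passes through composition
unchanged. Echo selection (shortest echo) is data handling, not logic.

## Lesion-level evaluation

Predicted probability maps are binarized (≥ 0.5 for single-class; argmax
with ties to the lowest class index for multiclass), decomposed into 3D
connected components (26-connectivity by default so diagonally adjacent
voxels of a small lesion do not fragment; 6-connectivity selectable), and
matched one-to-one to reference components greedily in ascending centroid
distance. A pair with distance strictly below the tolerance — 3 voxels for
CMBs, 5 for the larger and more dispersed iron deposits — is a true
positive; unmatched predictions and references are false positives and
false negatives. One-to-one matching prevents one reference lesion from
absorbing several predictions. Sensitivity and precision are computed per
participant; ratios with empty denominators are *undefined* (reported as
NaN, excluded from cohort averages, exclusions counted — optionally
imputed as 1 when both sets are empty). Cohort summaries: mean S and P
with SEM; magnitude accuracy √(S̄² + P̄²) reported in both averaging
orders (norm of the means and mean of per-participant norms), since the
two differ whenever performance varies across participants and the
intended order is ambiguous; Pearson correlation of per-participant lesion
burden (lesion count for CMBs, total labeled volume for iron deposits);
Bland–Altman mean difference with md ± 1.96·SD limits (sample SD); and
two-tailed Wilcoxon signed-rank tests between models, zeros dropped, exact
null where available. Voxel-level accuracy (TP+TN)/(TP+TN+FP+FN) is only
defined where TN exists, i.e. at voxel level.

## Phantom data

Real cohorts for this task cannot be redistributed, so the package
generates phantoms that emulate the relevant statistics rather than MR
physics:

* geometry — an ellipsoidal "brain" foreground with smooth tissue
  intensity (Gaussian random field) plus i.i.d. noise; a central ellipsoid
  stands in for the basal ganglia (no atlas in scope); voxels are
  1.0×1.0×1.5 mm (1.5 mm³), the only voxel volume recoverable from the
  emulated acquisition;
* CMBs — near-spherical clusters whose sizes follow a clipped log-normal
  with mean 4.18 voxels (the full size distribution is not published;
  log-normal is an assumption), placed anywhere in the interior,
  hypointense on SWI (−60 a.u., ≈12 noise SD) and paramagnetic on QSM
  (+0.12 a.u.);
* iron deposits — irregular clusters grown by seeded random walk to a
  log-normal size with mean 17.43 voxels, confined to the central region,
  SWI-hypointense and strongly paramagnetic (+0.30 a.u.);
* calcification mimics — clusters with the same SWI appearance but
  *negative* QSM (−0.25 a.u.), absent from the labels: a model can only
  reject them by using QSM;
* vessels — tubular SWI-hypointense random curves with neutral QSM, also
  unlabeled; where a vessel crosses the axial plane it mimics a CMB within
  the slice, reproducing a known false-positive source;
* QSM boundary artifact — a noisy shell at the foreground boundary
  (SD 0.25 a.u.) emulating the high-intensity boundary noise that real QSM
  reconstructions carry. This matters for fidelity of the preprocessing:
  it makes the ±5σ truncation behave as designed (clipping boundary spikes
  while leaving lesion values intact). Without it the phantom's σ_QSM is
  so small that truncation would clip the lesion values themselves and
  erase the CMB/iron contrast;
* cohort mixture — per-participant CMB counts: none with probability
  4/23, one or two with 13/23, three to eight with 6/23, plus an optional
  single outlier with 120 CMBs; iron deposits absent with probability
  5/24, else 2–13 lesions. Counts are clipped to a placement-capacity
  estimate that only binds for deliberately tiny test volumes. Lesions are
  placed with a two-voxel separation margin so every generated lesion is a
  distinct connected component and the ground-truth records equal the
  components recovered by the evaluation module exactly.

For testing SWI composition the generator also produces magnitude/phase
echo pairs: smooth positive magnitude, phase = optional low-frequency
background field plus focal negative-phase Gaussian dips, wrapped to
(−π, π].

What the phantom does **not** model: dipole physics (no susceptibility
convolution, so QSM and SWI are independent draws rather than linked
contrasts), k-space sampling and blooming, skull/CSF anatomy, partial
volume at lesion edges, scanner- and site-dependent intensity
distributions. Passing the end-to-end test therefore shows that the
pipeline — preprocessing, balancing, training, model selection, lesion
matching — is implemented coherently and can learn this class of contrast,
not that the network would reach any particular performance on clinical
data.

## Desk-scale problem sizes

The end-to-end test trains single-class CMB models on a 6-participant
phantom cohort of 32×32×16 volumes (32×32 slices), base width 8, SWI+QSM
input, 10 epochs per fold, Adam at lr 10⁻², batch 8, at most 640 training
samples per epoch, translations ±8; the full leave-one-out loop runs in a
few minutes on one CPU and its sensitivity/precision floor (0.5) is a
repository-calibrated bound for this setting. The acceptance script
recomputes the worked metric examples and the architecture constants,
which are exact.

## Known limitations

* Training at realistic scale (24 participants, 256×256 slices, 64-channel
  base width, 30 epochs) is supported by the code but not by the numpy
  backend's speed; desk-scale settings are the intended use here.
* BatchNorm inference uses running statistics; with very short training
  runs those lag the batch statistics, which can make early-epoch
  validation IoU pessimistic.
* The greedy centroid matching is order-deterministic but, like any greedy
  assignment, not guaranteed to maximize the number of matched pairs in
  adversarial geometries (ties at equal distance resolve by index).
* `truncate_qsm` is idempotent only with respect to the σ of its first
  pass; re-applying it recomputes a smaller σ.
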