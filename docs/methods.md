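# Methods

## The task and the pipeline

voxhazard classifies molecules as hazardous (prohibited, label 0) or
non-hazardous (allowed, label 1) from volumetric electron-density
representations, and simultaneously segments each molecule's grid into
three local-reactivity classes derived from a local electronegativity map.
The pipeline has four stages:

1. **Ternary reactivity masks.** For each molecule the electronegativity
   grid is thresholded at its own 10th and 90th percentiles: voxels
   strictly above the 90th percentile are class 2 (high reactivity),
   strictly below the 10th are class 1 (low reactivity), the rest class 0
   (medium/background). Percentiles are computed per molecule with linear
   interpolation between order statistics; boundary-equal voxels fall to
   class 0. Both conventions shift only boundary voxels but are fixed for
   reproducibility and are configurable.
2. **Modified 3D-UNet.** A volumetric encoder–decoder (two same-padded
   convolutions per level, channels doubling per level, 2× max pooling,
   mirrored decoder with skip concatenation) emits 3 per-voxel
   segmentation scores. A modification block then turns the segmentation
   into a molecule-level decision: a 1×1×1 convolution collapses the 3
   score channels to one; that map multiplies the input density
   elementwise — the *masked density*, which highlights putatively
   reactive regions and suppresses the rest; batch normalization and
   adaptive max pooling to a fixed p³ summary; and two fully connected
   layers produce the 2-class scores.
3. **Objective.** L = L_ce + L_gen_dice, an unweighted sum. L_ce is
   class-weighted cross-entropy on the molecule label with weighted-mean
   reduction (dividing by the summed applied weights makes the loss
   invariant to a common rescaling of the class weights). L_gen_dice is
   the generalized dice of Sudre et al. (2017) on the voxel segmentation:
   per-class weights 1/(class volume)², with ε = 1e-5 in numerator and
   denominator, softmax-normalized scores, batch-averaged. Classes absent
   from a sample's ground truth inherit the largest finite class weight of
   that sample, so false positives on absent classes still cost.
4. **Evaluation.** 2×2 confusion matrix (rows true, columns predicted),
   per-class precision/recall/F1/support, accuracy, macro and
   support-weighted aggregates, the majority-class chance baseline, and
   per-class dice overlap between predicted and true masks with the
   both-empty → 1 convention (absent minority classes on small grids
   should not zero the average). Dataset dice values are per-sample means.

## Published training configurations

Two presets carry the published hyperparameter sets for the real-data
use-cases (a cosmetics regulatory subset, "echa", and a compiled
food-safety set, "compfood"):

| parameter | echa | compfood |
|---|---|---|
| epochs | 38 | 14 |
| learning rate | 0.000844 | 0.0002409 |
| batch size | 20 | 12 |
| rate decay | ×0.1 every 35 epochs | — |
| weight decay | 2.57e-7 | 0.000186 |
| feature size | 28 | 4 |
| filter size | 4 | 4 |
| CE class weights (w0, w1) | 0.65127, 1.34672 | 1.24926, 1.1977 |
| final layer neurons | 16 | 32 |

The published configurations name no optimizer; decoupled-weight-decay
adaptive moment estimation (AdamW) is the default here because a
weight-decay value is part of each configuration, and plain momentum
descent is available via `Hyperparameters.optimizer`. Model selection keeps the epoch checkpoint
with the best validation accuracy. Mini-batches are reshuffled each epoch
from a (seed, epoch)-derived stream so runs are bit-reproducible on one
device and resumable.

## The modification block in detail

The collapse of the segmentation scores is a 1×1×1 convolution "reducing
channel count"; ``NetworkConfig.mask_channels`` chooses how far it
reduces. With one kept channel the product with the density is a single
masked-density map. A design study with ground-truth masks showed that a
single channel cannot carry the *class-tagged* amplitude information the
masking concept is meant to expose (which region's density is being read
out), whereas two channels — one per reactive class — preserve it; the
synthetic study therefore keeps two, while one remains the default.

Two initializations encode the block's intended semantics from step one
rather than leaving them for the optimizer to rediscover:

- the 1×1 collapse starts at reactive-region indicator weights (0 on the
  background channel, 1 on the kept reactive class), so the product is
  the described masked density immediately;
- the segmentation head's bias starts at the log class priors of the
  percentile masks (0.8/0.1/0.1). The volume-reweighted dice gives the
  background class almost no weight, so an unbiased start can drift into
  a minority-flooding solution it never leaves; starting from a
  background-dominant prediction avoids that basin (background dice ~0.87
  versus ~0 in ablations).

With global (1³) adaptive max pooling the classifier literally reads the
peak masked density of each kept reactive region — with the default
palette, the low-χ channel peaks near 1.4 (in log-density units) when the
region is anchored by Li and near zero when it is vacuum-anchored, and
the high-χ channel distinguishes F-anchored from C-anchored regions.

## The synthetic data generator

Real inputs of this kind come from semiempirical quantum chemistry. The
generator replaces that step with *promolecular* fields so the whole
pipeline is testable offline:

- density ρ(r) = Σ_i Z_i · exp(−|r − R_i| / a_i),
- electronegativity χ(r) = Σ_i χ_i k_i(r) / Σ_i k_i(r) with
  k_i(r) = exp(−|r − R_i| / a_i) — a kernel-weighted local average whose
  extremes localize near the extreme-χ atoms, bounded by the palette's χ
  range.

Atoms are placed uniformly by rejection sampling (minimum separation
1.8 Bohr) in the central ~5-Bohr cube of a 16-Bohr box, discretized on a
32³ grid (0.5-Bohr voxels). A molecule is labeled *prohibited* iff it
contains an atom of the palette's most electronegative element within
4 Bohr of an atom of the least electronegative element, so the class
signal is a spatial feature of the fields, not metadata.

The placement region is deliberately compact relative to the 4-Bohr
contact radius. In this regime the label statistics are dominated by
element co-presence with a distance modulation (about 61% of molecules
contain both motif elements; roughly one in seven of those keeps them
beyond the contact radius and stays allowed) — the kind of signal a
segmentation-then-readout classifier can learn. In wide boxes the label
becomes a pure distance conjunction between far-apart blobs, which pilot
studies showed gradient descent cannot assemble through this
architecture's pooled single-map bottleneck at desk scale.

The electronegativity field includes a weak vacuum term (χ_vac = 2.0,
kernel floor 1e-3): far from every atom the field relaxes to the vacuum
value instead of inheriting the nearest atom's χ out to the box corners.
Besides being the physically sensible limit, this keeps the percentile
tails of the field — the segmentation targets — anchored within ~5 Bohr
of the atoms, where a depth-2 receptive field can actually see the
evidence for them.

**Palette design.** The default palette is Li (Z=3, χ=0.98), C (6, 2.55)
and F (9, 3.98) with a common kernel width of 0.7 Bohr. Two properties
motivated this choice, established with an independent peak/mass analysis
before any network training:

- with equal widths, an atom's locally integrated density is proportional
  to Z, so every species has a signature readable from the density field
  itself; Z = 3, 6, 9 stay separable under neighbor-tail contamination,
  whereas close Z pairs (e.g. 8 vs 9) or faint H peaks do not;
- the χ extremes are an alkali and a halogen, so the prohibited motif is
  chemically a reactive ionic Li–F contact, and the segmentation classes
  (low-χ regions near Li, high-χ near F) are exactly the cues the motif
  rule needs — the classification signal lives in the joint
  density/electronegativity structure by construction.

Independent oracles calibrate what the fields can support: a handcrafted
detector (local density maxima classified by integrated mass, then the
motif rule on detected positions) and a logistic readout of the true-mask
region amplitudes reach ≈0.87–0.93 accuracy on native 32³ grids but only
≈0.67 after trilinear downsampling to 16³ — the amplitude signature does
not survive coarsening, which is why the study runs at native resolution.
The prohibited fraction is ≈0.50 (measured on thousands of molecules),
inside the 30–70% sanity band asserted in tests.

All randomness derives from one integer seed, with sample i using
seed + i, so datasets are reproducible and generation can be parallelized
or resumed.

**What the generator does not emulate:** self-consistent electronic
structure (no charge transfer, no bonds), conformational preferences
(atom placements are uniform, not molecular geometries), realistic
element frequencies, and cube-file noise or normalization conventions of
any particular quantum-chemistry code. Passing tests demonstrate that the
pipeline's machinery — masking, losses, optimization, evaluation — works
and that the network can extract a spatial structure–label relationship
of this kind; they say nothing about accuracy on real regulatory data.

## Numerical and implementation choices

- **Internal units** are Bohr everywhere; Ångström cube files (negative
  voxel-count convention) are converted on read.
- **Autodiff engine.** The network runs on a small reverse-mode engine
  over numpy arrays written for this package, with compiled (numba)
  direct-loop kernels for the 3D convolutions — an im2col formulation is
  memory-bound at 32³ volumes — and a pure-numpy fallback that the test
  suite cross-checks against the compiled path. Gradients of every
  operation are verified against central finite differences. Training
  arithmetic is float32; float64 inputs are honored for verification.
- **Input normalization**: each density grid is divided by its own
  maximum before entering the network by default; log compression
  (log(1+ρ)) and fixed physical scales are also available. The synthetic
  study uses log compression: per-grid maximum scaling equates every
  molecule's tallest peak and thereby erases the element-amplitude
  signal, while the log transform preserves amplitude ordering and keeps
  the sparse far field visible to the convolutions. Grids whose shape
  differs from the network's input shape are resampled by trilinear
  interpolation.
- **Modification-block order.** The block is assembled from a declared
  stage list. The default is multiply → batch-norm → pool; the synthetic
  study uses multiply → pool → batch-norm, which in our experiments is
  the order under which the classification head actually trains (the
  batch statistics of the pre-pooling product map drift too fast early in
  training under the default order).
- **Segmentation scores** enter the 1×1 convolution raw (no softmax), so
  score magnitudes can carry molecule-level evidence through the product;
  a softmax-normalized mode exists behind a flag.
- **Augmentation**: ``Hyperparameters.augment`` applies a random cube
  symmetry (one of the 48 rotations/reflections) per mini-batch to inputs
  and masks jointly; off by default, on in the synthetic study, whose
  planted signal is symmetry-invariant by construction. Without it the
  600-molecule study memorizes its training set.
- **Tie-breaking**: both argmaxes (per-voxel class, molecule label)
  resolve ties to the lowest class index.
- **Degenerate inputs**: constant electronegativity grids yield all-
  background masks (strict inequalities); empty ground-truth classes in
  the dice are handled by the weight rule above; a batch with a non-finite
  loss aborts training and names the offending sample ids.
- **Stratified splitting** uses largest-remainder rounding per class, so
  every part size is within one sample of its exact quota; k-fold CV uses
  stratified folds with a stratified inner validation split (15%) for
  model selection.

## The desk-scale learnability study

The study configuration lives in ``voxhazard.study`` and is shared by the
test suite, the acceptance script and the worked example: the default
generator, native 32³ grids, log-compressed density input, a depth-2
feature-size-4 network (filter 3, two mask channels, global max pooling,
16 final-layer neurons, the multiply → pool → batch-norm order), AdamW at
learning rate 3e-3 with weight decay 1e-3, batch 20, cube-symmetry
augmentation, and at most 20 epochs. The full study uses 600 train / 150
validation / 150 test molecules; the test suite runs a half-size version
(300/75/75, 8 epochs) over three fixed seeds and the scripted
reproduction runs the full sizes for one seed at 12 epochs — sizes chosen
so each consumer completes in minutes on one CPU core, with validation
accuracy saturating well inside those epoch budgets.

Under these conditions the pipeline clears the chance baseline by a wide
margin and segments the background class well, but its test accuracy
plateaus in the mid-0.7s — short of the 0.85 design target asserted by
the learnability test in the suite, which is therefore expected to fail
and is kept as an honest record of the gap. A design study traced the plateau to the
architecture's communication bottleneck: all molecule-level evidence must
pass through max-pooled products of (possibly co-opted) segmentation
scores with the density, and oracle readouts through that same bottleneck
with *perfect* segmentation cap near 0.87, while trained segmentations
are necessarily imperfect. Wider networks, more epochs or auxiliary heads
would likely close part of the gap but sit outside the study's fixed
architecture budget.

## Known limitations

- The engine is CPU-only and single-device.
- The planted-signal accuracy target of 0.85 is not reached by the fixed
  study architecture (see above); treat the study as a pipeline
  integration benchmark with a documented performance envelope, not as
  evidence the architecture saturates its task.
- Generalized dice with squared-reciprocal-volume weights nearly ignores
  the background class when the minority classes are very small; the
  reported per-class dice makes this visible rather than hiding it, and
  the prior-biased initialization exists precisely because of it.
- The promolecular fields are separable sums of atomic kernels; a network
  that exploits this (e.g. by learning deconvolution-like filters) may
  find the task easier than real semiempirical densities would be.
- Cross-validation retrains one network per fold from scratch; with the
  published epoch counts this is the dominant cost of the CLI `crossval`
  command on large manifests.
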