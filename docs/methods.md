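# Methods

## Phantom model

Downstream stages need images with mammogram-like second-order statistics
and class-dependent lesion features, not radiological realism. The
background is an isotropic Gaussian random field with power spectrum
∝ 1/f^β, β = 3.0 by default — the standard "lumpy background" approximation
to fibroglandular tissue texture — min–max rescaled to [0.2, 0.8] so lesion
contrast never clips at the background level. The four diagnostic classes
add, on top of this field:

| class | lesion | mask |
|---|---|---|
| normal | none | empty |
| benign_no_callback | one sharp disc, radius 8–12 px, contrast +0.10 | the disc |
| benign | one Gaussian mass, σ 6–10 px, contrast +0.18 | half-maximum disc |
| cancer | 5–15 Gaussian blobs (σ 1–2 px, contrast +0.35) in a 12-px disc | the 12-px disc |

All lesion parameters are stand-ins chosen once for texture-statistics
separability between classes (the cancer cluster mimics the high-frequency
signature of a microcalcification cluster; the benign masses are low-pass
bumps). They are **not** fitted to any measured lesion population, and
passing tests on these phantoms demonstrates machinery correctness, not
performance on clinical images: real mammograms have anisotropic structure,
scanner noise, skin lines and pectoral muscle, none of which the generator
emulates. Lesion centers are drawn uniformly inside a margin that keeps the
lesion wholly in frame; on images too small for the margin the center
collapses to the middle.

Seed fan-out everywhere uses one scheme: child = first word of
`numpy.random.SeedSequence([master, *key])`, reduced mod 2³¹. SeedSequence's
mixing is specified by numpy and platform-stable, so a master seed
reproduces every phantom, weight bank, noise image and trial order
bit-identically.

## Feature hierarchy

The default desk-scale network is conv3×3(8)+ReLU → avg-pool2 →
conv3×3(16)+ReLU → avg-pool2 → conv3×3(32)+ReLU, single input channel,
same-size zero padding, pooling floor-dividing spatial dims. Gram
statistics are taken at the three ReLU outputs, giving receptive fields of
3, 8 and 18 pixels — a genuine hierarchy while staying synthesizable on one
CPU core in well under a second per image. Average pooling is the default
because its gradient is smooth, which helps pixel optimization; max pooling
is available per layer. Conv weights are seeded Gaussians with std
1/√fan_in (stable activation scale without training); dense layers
initialize lazily on first forward because their fan-in depends on input
resolution, from a stream keyed by (weight_seed, layer index) so they are
equally deterministic. A 19-weight-layer VGG-style configuration ships
under `configs/` for architecture parity; its pretrained weights are out of
scope and nothing at run time requires it.

Forward and reverse passes are written directly in numpy (im2col
convolution; hand-derived gradients for conv, pooling, ReLU and dense),
which keeps the whole pipeline dependency-light and bit-reproducible and
gives the synthesizer exact pixel gradients.

### Fine-tuning

The miniature fine-tune attaches a linear softmax head to the final feature
layer and runs full-batch gradient descent on mean multinomial
cross-entropy, backpropagating into every conv weight. It is a
proof-of-function stand-in for large-scale transfer learning: with 80
phantoms (20 per class, 32×32), 30 epochs and learning rate 0.1 it lifts
held-out 4-way accuracy to ≈ 0.38 against the 0.25 chance level.
Learning rates around 1.0 destabilize training at this scale.

## Synthesis objective and optimizer

Raw (unnormalized) Gram matrices `G^l = F^l F^lᵀ`; objective
`L = Σ_l w_l /(4 N_l² M_l²) Σ_ij (G^l − A^l)²_ij`. The 1/(4 N² M²)
normalization makes layers of different widths commensurate; layer weights
default to uniform 1/L. The optimizer is projected steepest descent with
Armijo backtracking (c = 1e−4, shrink 0.5, first trial step 1.0, accepted
steps double the next trial step): a trial point is
`clip(x − t·g, 0, 1)` and is accepted when the *post-projection* loss
satisfies sufficient decrease `f(x⁺) ≤ f(x) − (c/t)‖x − x⁺‖²`, so the
recorded trajectory is non-increasing by construction. Initialization is
seeded uniform white noise on [0, 1] (matching the pixel range); stopping
at `max_iters` (default 500) or loss ≤ tol (default 1e−6). No
post-processing (e.g. histogram matching) is applied to synthesized images.
On 32×32 phantoms with the desk net the loss typically falls below 1% of
its initial value within a few dozen iterations while the mean absolute
pixel difference from the original stays above 0.05 — statistics matched,
pixels not.

`gram_distance` is the same loss at uniform weights, used as a symmetric
texture dissimilarity for class-fidelity checks.

### Gradient verification

`gradient_check` compares the analytic backprop gradient against central
finite differences (default h = 1e−3), normalized by the larger max-norm of
the two gradients. Pixels whose ±h stencil flips any ReLU active set are
excluded: the objective is non-differentiable there and a central
difference is not a valid derivative estimate (the same differentiability
requirement standard numerical gradient checkers impose). Typically ≥ 90%
of an 8×8 image's pixels are checkable and agree to ~1e−6.

## Patch extraction

ROI-centered crops place a w×w square (600 px at full scale; half-open
0-based intervals) at the rounded mass centroid of the ROI — the centroid
is used because the annotation convention defines no center; it is unique
and orientation-free. Extraction is declined, with a machine-readable
reason, when (checked in this order) the mask has ≠ 1 eight-connected
components, the square would leave the image, or any ROI pixel falls
outside the square. No padding is ever fabricated for ROI crops; for
saliency crops on normal images the square is instead clamped inside the
bounds, because unannotated images must always yield a patch to preserve
class balance — a deliberate asymmetry.

Saliency is a single-channel center–surround intensity-contrast map:
`S = smooth(Σ_{σ∈{1,2,4}} maxnorm(|G_σ∗I − G_{4σ}∗I|))` with final Gaussian
smoothing σ = 2 and max normalization, a minimal intensity-channel
simplification of the classic bottom-up conspicuity model (color and
orientation channels carry no information for grayscale mammograms). The
"most salient region" is the 8-connected component of pixels ≥ 0.9 × max
containing the global argmax; the crop centers on the argmax, row-major
first index on ties.

## Simulated psychophysics

Experiment-1 schedules present each of the 2k images exactly
`min_presentations` times (default 10), giving an exact 50–50
original/synthesized truth split by construction; Experiment-2 schedules
enumerate all unordered image pairs including identical pairs (36 pairs
for k = 4) the same number of times. Orders are seeded uniform shuffles.

The detection observer is the equal-variance Gaussian SDT model; the rater
holds latent dissimilarities d_pair = 10, d_class = 45, d_diff = 80 with
rating noise σ = 10 (clamped to the 0–100 scale). These latent values are
the package's chosen emulation of the qualitative rating structure —
twins rated very similar, same-class non-twins intermediate, cross-class
pairs dissimilar; they are not fitted to human data.

d′ uses the log-linear correction (h + 0.5)/(n + 1) so ceiling/floor
observers stay finite, in both task framings (hits vs false alarms, and
the complementary true negatives vs misses, which coincide at equal trial
counts). RDM entries are mean ratings pooled over presentation order
(side-by-side display has no order semantics), diagonal fixed at 0.
Congruity is the Spearman correlation of upper triangles against a joint
row/column label-permutation null, p = (1 + #{ρ_perm ≥ ρ})/(n_perm + 1)
with n_perm = 1000 by default (the +1 keeps p unbiased and nonzero).
Clustering is average linkage on the RDM (scipy implementation, verified
against a brute-force oracle in the tests). The paired comparison
aggregates per subject: mean rating of trials involving each original
minus mean rating of trials involving its twin, twin-pair trials excluded
from both sides; two-sided t with df = n_subjects − 1. All-zero
differences return t = 0; zero-variance nonzero differences are reported
as a degenerate-data error rather than an infinite statistic. A binomial
test on response counts is *not* shipped for per-subject d′ significance;
the d′ values themselves are the deliverable.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen so
the full pipeline stays a seconds-to-minutes affair on one core: 32×32
synthesis images with the three-layer net, 10–20 synthesis runs per check,
200 simulated observers per d′ recovery level, 100–200 permutation-test
replicates at 100–200 permutations each, and 64–128 px phantoms for
extraction checks (1024 px for the full-scale 600-px crop geometry). The
CLI defaults (`--size 600` for extraction, 500 synthesis iterations) match
the full-scale procedure.

## Known limitations

- Phantoms are stationary Gaussian fields plus parametric lesions; no
  claim of radiological realism, dose physics, or scanner noise.
- The desk network is untrained (seeded random weights); synthesized
  phantom textures are Gram-metamers of the *random-feature* statistics,
  which suffices for machinery validation but does not reproduce the
  visual quality attainable with a large pretrained hierarchy.
- The fine-tuning loop is full-batch steepest descent with a linear head —
  a functional miniature, not a performant trainer.
- Rating simulation assumes a single shared latent structure across
  subjects plus independent Gaussian noise; real raters drift and
  disagree systematically.
- Reaction times are carried as a field in trial records but never
  modeled or analyzed.
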