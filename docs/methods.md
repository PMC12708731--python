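# Methods

## Problem setting

Tumor characterisation from whole-slide histopathology images is inherently
multiscale: glandular and stromal context is visible at low objective power
(10x) while nuclear morphology needs high power (40x). `histomulti`
implements five mechanisms that couple the two views during training of a
patch classifier, together with a synthetic data generator that makes every
mechanism exercisable — and its claimed effect measurable — on a laptop CPU,
without access to real slides.

All tensors are float64 and all differentiable computation runs on a small
in-package reverse-mode automatic-differentiation engine
(`histomulti._tensor`). This keeps the dependency surface to the standard
scientific Python stack and makes every analytic gradient directly checkable
against central finite differences (the test suite does this for each loss
at relative error < 1e-4).

## The five mechanisms

**Uncertainty-aware cross-magnification consistency (PAUAC).** Each branch
carries a Monte-Carlo-dropout classification head: T stochastic passes with
independent dropout masks (default T = 10, dropout 0.3, applied in the heads
only) whose softmax outputs are averaged into a predictive distribution
P(i), with Shannon predictive entropy H(i) as the uncertainty measure. The
consistency loss is mean_j w_j · KL(P_j(10x) || P_j(40x)) with
w_j = exp(−α(H_j(10x) + H_j(40x))). Conventions fixed here: KL uses natural
log with a 1e-12 floor on the denominator distribution; entropies are
reported in bits (the curriculum threshold convention) but converted to nats
inside the weight so α shares the KL's scale; the aggregation over units is
a mean, so the loss magnitude is batch-size invariant and the composite
weight λ is transferable; the KL direction is 10x→40x by default with a
symmetric option; α defaults to 1.0. Units are whole patches by default; a
dense per-pixel mode resamples the 40x map onto the co-registered 10x crop
by nearest neighbour.

**Structural attention-constrained graph regularisation (SACGR).** SLIC
superpixels of the 40x patch form a tissue graph: edges join superpixels
sharing a 4-connected pixel boundary, weighted by a Gaussian kernel on
mean-color distance (bandwidth 0.2·255 by default), sparsified to at most 8
neighbours per node, re-symmetrised by the elementwise max and
row-normalised. ViT tokens are assigned to superpixels by majority footprint
overlap. The transformer's last-layer, head-averaged attention is
symmetrised and pooled to node pairs by the mean over member-token pairs,
diagonal-zeroed and row-normalised; the structural loss is the mean squared
difference between the two adjacencies over ordered off-diagonal pairs
(a mean rather than a bare sum, again for size invariance; both matrices are
row-normalised because attention and adjacency otherwise live on different
scales). A companion smoothness term, Σ_{i<j} A_ij‖f_i − f_j‖² / Σ_{i<j}
A_ij on node-mean token features, is added with weight 0.1·λ_sacgr by
default. How token-level attention becomes a superpixel matrix is this
package's construction; the pooling is checked against a brute-force
token-pair loop in the tests.

**Curriculum scheduling (MPCS).** Patch complexity is
ξ = λ¹·E + λ²·σ²_nuc, with E the Shannon entropy (bits, 256-bin histogram)
of the integer grayscale luminance (0.299R + 0.587G + 0.114B) and σ²_nuc the
population variance of nuclei-per-pixel densities over an 8×8 subtile grid.
Defaults λ¹ = 1, λ² = 1000 put both terms on an O(1) scale at the operating
thresholds of 4.1 bits and 1.3e-3. Selection probability is the sigmoid
1/(1 + exp(−β(ξ − μ_t))) with β = 1; the threshold μ_t is the empirical
ξ-quantile at a level that ramps linearly (0.2 → 0.8 by default) over the
first part of training. Batch sampling is weighted without replacement: at
epoch 0 weights are 1 − P_select + floor (easy samples dominate), blending
linearly into P_select + floor across the ramp and staying there after it.
The blend, rather than a hard phase switch, is what makes the mean sampled
complexity rise monotonically on pools where the two ξ terms are bimodal —
a hard switch provably dips mid-ramp on such pools. A small floor
probability (0.05) keeps every sample reachable. Pure "anti" and "pro"
weightings are exposed as config modes.

**Voronoi-morphometry fusion (TDMM).** Nuclei centroids induce a discrete
Voronoi tessellation (exact nearest-centroid per pixel, ties to the lowest
centroid index, computed by chunked brute force — on a raster grid the brute
force is the ground truth, so no polygon geometry is needed). Three
channels, each min–max normalised per patch: owning-region area, distance to
the nearest centroid, and owning-region neighbour count (4-adjacency of the
ownership map). The channel set is this package's choice of morphometry
features; it is config-extensible. The morphometry map is tokenised by a
second (weight-independent) copy of the patch tokeniser, and fused with the
image tokens by single-head scaled-dot-product cross-attention — Q from
image tokens, K and V from morphometry tokens, scores scaled by 1/√d_k —
followed by mean pooling and a two-layer MLP softmax head. Patches with no
centroids produce an all-zero map with an explicit empty flag.

**Positional contrastive alignment (CCCRA).** Projected embeddings of the
same patch at 10x and 40x are a positive pair; every other patch's
opposite-view embedding in the batch is a negative (the denominator includes
the positive). The score for a candidate is
[cos(z_i, z_k) + γ·cos(p_i, p_k)]/τ with γ = 0.3 and τ = 0.07; both terms
share the temperature, the standard InfoNCE placement. Positions are
normalised (row, col) in [0,1]², shifted to offsets around the patch centre
before the cosine (raw coordinates are all-positive and would make every
positional cosine near 1); an exactly-central position has a zero offset and
contributes positional similarity 0.

**Composite objective.** L_total = L_sup + λ¹L_PAUAC + λ²L_SACGR +
λ³L_CCCRA with defaults λ¹ = 1.0, λ² = 0.5, λ³ = 0.5, plus the smoothness
term with its own weight. Ablation modes zero exactly one λ.

## Synthetic data generator

The generator emulates what the pipeline needs from co-registered slide
patches and nothing more. One high-resolution canvas per pair: an
eosin-pink background with smoothed low-frequency Gaussian texture (so
texture entropy is non-trivial), filled elliptical hematoxylin-purple nuclei
with per-nucleus color jitter, and — for a `tumor_fraction` share of pairs —
a random elliptical tumor blob containing denser, larger, more pleomorphic
nuclei (radius/eccentricity spread scaled by the `pleomorphism` factor).
The 40x patch is the central canvas crop at native resolution; the 10x patch
is the 4x block-mean downsample of the full canvas (4x linear scale matches
the objective ratio, and the 40x field of view is the central quarter-side
region of the 10x patch). Because both views derive from the same canvas,
the co-registration residual is pure rounding: measured mean absolute
channel error is ≈ 0.25/255, far inside the 8/255 contract. Ground truth:
binary masks at both scales (8-bit PNG, 255 = tumor), a centroid table in
40x-frame coordinates (0-based, origin top-left, x = column), and a patch
label defined as tumor iff the 40x mask has any positive pixel (blob centres
are drawn inside the 40x field of view so label and mask agree).
Defaults: 512-px canvas, 150 background nuclei, 200 blob nuclei,
tumor_fraction 0.5, nucleus radius 6 ± 1 px at 40x, pleomorphism 1.5,
pixel noise σ = 6.

What the generator does not emulate: stain physics, scanner optics and
artifacts (folds, bubbles), realistic tissue architecture (glands, stroma),
or inter-site stain variability. Passing tests therefore demonstrate that
the losses, scheduler and metrics behave as specified and that each
mechanism moves its own target quantity on data where the relevant signal
exists — not that the pipeline reaches any particular accuracy on real
slides.

## Reference encoders and trainer

Backbones are pluggable; the in-package references are deliberately tiny. A
purely convolutional context branch (total stride 8) for 10x, and a small
ViT (patch tokeniser + learned positions + pre-LN transformer blocks) for
40x that exposes every layer/head attention matrix. Paper-scale widths
(hidden 768, 12 heads) are config options; the test configuration is hidden
32–64, 4 heads, 1–2 layers on 32–64 px inputs so a full forward runs in
milliseconds.

Training uses AdamW (lr 1e-4, weight decay 0.01, betas 0.9/0.999 by
default) with linear warm-up then cosine decay, curriculum-weighted batch
sampling, and MC heads with T = 10 passes. Everything is seeded — parameter
init, dropout masks, batch composition — so runs are bit-reproducible. The
desk-scale study configuration used by the tests and the acceptance script
is 200 pairs at a 128-px canvas (32×32 patches), lr 3e-3, 8 epochs, warm-up
2, batch 16: at this model size the paper-scale learning rate is
unnecessarily conservative, and 8 epochs suffice for the supervised task to
saturate while the regulariser effects remain measurable. Early stopping
tracks validation AUC (the model emits patch labels, not masks; with dense
predictions it would track Dice). Checkpoints are numpy `.npz` archives and
round-trip bit-identically.

Evaluation: Dice and Mann-Whitney AUC as standard; cross-magnification NMI
clusters each view's embeddings with seeded k-means (k = class count, 10
restarts) and scores agreement — the clustering recipe is this package's
construction; attention precision takes pixels in descending attention order
until 20% of total mass is covered and returns the precision of that set
against the target mask, with boundary ties credited at their group's
expected target fraction so the result is tie-order independent.

## Numerical choices and degenerate inputs

KL and log computations floor their arguments at 1e-12; softmax subtracts
the row max; cosine similarity raises on vectors with norm ≤ 1e-12 (and
positional similarity is defined as 0 for exactly-central offsets);
min–max normalisation of a constant channel yields zeros; superpixel nodes
with no assigned tokens are excluded from the smoothness term with a logged
warning; a patch with no centroids yields a zero morphometry map with
`empty_flag`; two empty masks have Dice 1.0 by convention; subtile grids
that do not divide the patch absorb the remainder in the last row/column.

## Directional ablation findings (synthetic, desk scale)

Over 3 seeds on the 200-pair pool, comparing medians of final validation
metrics: removing PAUAC raises cross-magnification KL by roughly two orders
of magnitude; removing SACGR raises off-graph attention mass (consistently
in every seed, though the margin is small at this model scale because the
attention drift in 8 epochs is itself small); removing CCCRA collapses
cross-magnification NMI from ≈ 0.86 to ≈ 0.11. These are direction-of-effect
results on synthetic data, not effect-size claims about real slides.

## Known limitations

The autodiff engine is eager and unoptimised; paper-scale configurations
(768-dim, 12 heads, 512-px patches) type-check but are not practical to
train with it. The SLIC implementation delegated to scikit-image can merge
away very small requested segment counts (k = 2 on small images collapses
to one segment); the grid method is the predictable fallback. The NMI and
attention-precision recipes, the morphometry channel set, and the
attention-to-superpixel pooling are reasonable constructions where the
mechanism itself is underspecified in the literature; alternatives would
shift absolute values but not the directional contracts the tests assert.
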