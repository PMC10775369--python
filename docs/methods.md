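# Methods

`mifpipe` analyzes cyclic multiplexed immunofluorescence (mIF) image
stacks: a specimen is repeatedly stained, imaged over several fields of
view (FOVs) and fluorescent channels, quenched, and re-imaged, so that a
panel of tens of protein markers is built up over N cycles. The pipeline
turns the raw stain/quench TIFF grid into aligned stacks, per-cell
instance masks, a cells × markers table, rule-based immune phenotype
calls, and unsupervised clusters.

## Data model and pre-processing

An acquisition is the complete grid FOV i × cycle j × channel c of
stain/quench image pairs plus a manifest mapping (cycle, channel) to a
marker name. Pixel-level pre-processing is a fixed three-step chain per
stain image:

1. **Quench subtraction.** The paired post-quench image is a per-pixel
   background estimate (autofluorescence plus residual signal);
   `out = max(stain − quench, 0)`.
2. **Percentile normalization.** Intensities are rescaled to [0, 1]
   between the image's 25th and 99th percentiles (clipped outside).
   Percentiles are computed over the full image including background.
3. **Gaussian denoising.** A σ = 1 px Gaussian blur (reflective borders;
   σ is configurable, and σ = 0 is the identity) suppresses impulse
   noise.

**Two intensity scales.** The normalized scale feeds registration and
segmentation, which need channel-comparable contrast. Marker
*quantification*, however, aggregates the background-subtracted,
denoised, **unnormalized** intensities: on a nearly-empty channel (a rare
marker occupying < 1% of pixels) the 99th percentile anchors to the
background level, which saturates negative cells toward the positive
ceiling and destroys the on/off contrast that positivity calling needs.
This split is a deliberate design decision, verified on synthetic data.

## Registration

Slides are physically removed and remounted between cycles, producing a
rigid translation per cycle that is shared by all FOVs of that cycle.
One designated FOV per cycle therefore suffices:

- the C channel images of each cycle are collapsed by per-pixel maximum
  projection (cells visible in any channel become anchors) and
  downsampled 2×;
- a foreground mask keeps cell-sized objects: Otsu threshold, 3×3
  morphological opening, connected components filtered to areas within a
  size band (default 10–2000 downsampled px²). Fewer than `min_objects`
  (default 5) objects in either image fails the cycle with
  "low cellularity";
- over t = 3 trials, image and mask are cropped by a random window of
  0.75 per axis (the same window for reference and moving image), and
  the translation is the peak of the masked normalized cross-correlation
  (Padfield's Fourier-accelerated method as implemented in
  scikit-image). The mask restricts the correlation to cell pixels,
  making it robust to debris;
- trial shifts farther than 4 downsampled px (Chebyshev) from the
  component-wise trial median are discarded; the mean of the survivors,
  scaled back ×2 and rounded to integers, is the cycle's shift. No
  surviving trials fails the cycle with "unstable correlation".

Shifts are integer-valued at the downsampled grid, so full-resolution
estimates are quantized to one grid step: noise-free errors are bounded
by 2 px, and correlation plateaus can break a half-step tie to either
neighbor. An optional ±2 px full-resolution refinement pass (off by
default) removes this quantization and recovers noise-free shifts
exactly. The
orchestrator retries failed cycles with the remaining FOVs before giving
up on a cycle; a cycle that stays failed is excluded downstream (its
markers are dropped, and gating rules that need them are disabled and
reported).

Aligned images are produced by translating each cycle back onto the
reference frame with zero-filled vacated borders. Because border pixels
are unobserved in some cycles, cells whose centroid lies within
max |shift| of the FOV edge are dropped at profiling.

Design note: the masked correlation needs intensity *variation* among
cells — on constant-intensity binary scenes any cell overlays any other
equally well and the peak is ambiguous. Real stains (and the generator)
vary per-cell brightness.

## Segmentation

A three-class formulation — background, cell interior, cell boundary —
keeps touching cells separable: interiors of distinct cells are never
4-connected because a boundary ridge always separates them.

**Ground-truth construction.** From an instance label map, a pixel is
interior when every pixel within `boundary_width = 2` px (Chebyshev) has
the same instance label; other instance pixels are boundary. The width
is a package choice: 2 px keeps the boundary class a few percent of
pixels on cell-scale tiles while surviving the round trip for touching
pairs.

**Instance extraction** inverts this: 4-connected components of
predicted interior seed labels, each seed grows through the boundary
ring by watershed on the distance-to-seed transform, and components
below `min_area` (default 10 px²) are removed; labels are renumbered
1..K.

**Network.** A U-Net-style shared encoder (two 3×3 conv + ReLU per
level, 2× max-pooling, default depth 4, base 32 filters) feeds three
heads: a skip-connected decoder producing 3-class softmax logits at
input resolution; a count regressor (global average pool → dense →
softplus) predicting the number of instances intersecting the tile; and
an auto-encoding decoder (no skips) reconstructing the 2-channel input
from the bottleneck, which regularizes the shared features. Inputs are
the CD45 (pan-leukocyte) and DAPI (nuclear) channels, normalized. The
implementation is a compact numpy layer library with explicit
backpropagation (im2col convolutions over BLAS, Adam optimizer); batch
norm is omitted — He-initialized conv + ReLU trains the task well and
keeps the backward pass simple. Inputs whose size is not a multiple of
2^depth are reflect-padded internally and outputs cropped back.

**Loss.**

    L = Lce + α·Ljacc + λc·Lcount + λa·Lauto + β·Lreg

- `Lce`: pixel cross-entropy, mean over pixels of w(px)·(−log p_true),
  with class weights (1, 3, 3) against background dominance and a
  further ×2 on boundary pixels currently argmax-predicted as interior.
  That multiplier is a constant recomputed each forward pass (a
  stop-gradient importance weight, not a differentiable confusion term).
- `Ljacc`: soft per-class Jaccard, `1 − (Σp·y + ε)/(Σp + Σy − Σp·y + ε)`
  with ε = 1e−7, averaged over the three classes; probabilistic rather
  than thresholded for differentiability.
- `Lcount`: squared error of the count head against the number of
  distinct instance labels intersecting the tile.
- `Lauto`: mean squared reconstruction error.
- `Lreg`: Σw² over all conv/dense weights (biases excluded).

Default weights α = 1e3, λc = 1e3, λa = 0.5, β = 1e−4, with the default
training schedule of 700 epochs, batch 16, Adam at 1e−5, on 300×300
tiles with 20% overlap. Tiles with no labeled cells are removed from the
training split; augmentation applies stochastic 90° rotations, flips
(identically to image and label mask), additive Gaussian noise and a
global mean shift (image only). The best checkpoint by validation pixel
accuracy is kept; an optional restarts mode trains several independently
seeded models and keeps the best.

**Scaled training recipe.** All validation and acceptance runs use a
small CPU-friendly configuration chosen as the package's own scaled
problem: 64 px tiles from 512² synthetic FOVs (≈ 480 non-empty tiles,
80/20 split by FOV), a depth-2 net with 8 base filters, 14 epochs of
Adam at 5e−4, and rebalanced weights α = 2, λc = 0.01, λa = 0.1,
β = 1e−5 (with ~5 cells per 64 px tile, the default-scale λc would let the
count head's early error dominate the shared encoder's gradients). This
recipe reaches held-out mean per-class pixel F1 ≈ 0.97 and recovers
planted instance counts within a few percent in about five minutes on
one core. Loss *formulas* are always validated at the default weights.

**Inference** tiles the FOV, averages softmax probabilities in overlap
regions (seam-free and deterministic; not logit averaging or
center-cropping) and takes the per-pixel argmax.

## Single-cell profiling

Marker images aligned to the reference frame are aggregated per cell:
mean intensity over the cell's full pixel set (interior plus its claimed
boundary pixels), with area and centroid recorded. The table then goes
through:

1. **Outlier removal** (optional): cells above `median + k·MAD` (k = 5)
   for any marker are dropped — high side only, targeting saturated
   debris. MAD is the median absolute deviation from the median; when
   MAD = 0 any value strictly above the median counts, so an all-equal
   column removes nothing. Caveat: on panels where a marker has a clean
   minority of strongly positive cells this filter removes exactly those
   positive cells (median and MAD describe the negative majority);
   disable it (`mad_k=None`) or raise k for well-separated mixtures.
2. **Log transform**: x → ln(x + 1e−6); a state machine prevents double
   application.
3. **Positivity thresholds**, two modes on the log scale:
   - `mean_minus_3sd` (default): threshold = mean − 3·sd over all cells.
     Appropriate for markers expressed by essentially all cells (e.g.
     CD45 after immune gating) where only a sparse negative tail must be
     cut. On a genuine on/off mixture the mixture variance pushes this
     cutoff below the negative population and every cell comes out
     positive — hence the second mode.
   - `otsu`: a bimodality test (two- vs one-component Gaussian mixture,
     BIC margin 10) decides whether the marker splits. Bimodal markers
     get an Otsu cut refined by a 1-D 2-means iteration (Otsu's split
     can sit at a cluster edge when the inter-mode gap is wide);
     unimodal markers are classified pan-positive (mean − 3·sd) or
     absent (all negative) by comparing their mode to the panel-wide mid
     intensity. Synthetic validation uses this mode, since its planted
     mixtures are exactly the case the default rule cannot split.
4. **Phenotype assignment**: cells are gated through an ordered table of
   marker combinations (positive set / negative set), most specific
   first, first match wins — CD4+ T cells (CD45+CD3+CD4+, CD11b−),
   CD8+ T cells, NK cells, B cells, neutrophils, macrophages, dendritic
   cells, then generic "Immune cells" (CD45+, CK56−) as fallback; cells
   matching nothing (in particular CD45−) stay "unassigned". Overlap
   between rules (e.g. a CD66b+CD68+ cell) is resolved by that fixed
   precedence.
5. **Z-scoring** per marker for visualization; constant markers map
   to 0.

## Clustering

The z-scored log table is projected to 2-D with UMAP (n_neighbors = 15,
min_dist = 0.1, Euclidean metric, fixed seed; the label-supervised
variant implements "pull predefined phenotypes together" and is
optional). HDBSCAN on the embedding assigns density-based clusters with
noise = −1; `min_cluster_size` defaults to max(10, 1% of cells), and the
hierarchy root may be selected so a genuinely single-cluster dataset is
not reported as all noise. Summaries: per-cluster marker means z-scored
across clusters, and a phenotype × cluster contingency table.

## Synthetic data: what it emulates, and what it does not

The generator plants everything downstream stages must recover. Cells
are soft-edged disks (flat core, ~1 px Gaussian rim) with a concentric
nuclear disk at 0.7× the cell radius; channel 0 of *every* cycle images
the nuclear counterstain (as real cyclic protocols re-image DAPI each
cycle — it is the registration anchor), and the remaining slots walk the
protein panel. Phenotypes are drawn from a configurable mixture
(defaults follow the observed abundance ordering: neutrophils and
macrophages common, NK and dendritic cells rare) and determine which
markers are "on". Per-cell marker levels are Gaussian around the on/off
means with a coefficient of variation of 25% (15% for DAPI), truncated
at ±2σ so the populations stay separated; defaults are on = 2500,
off = 100, DAPI = 3000 over a background of 200 with noise σ = 30, in
arbitrary 16-bit-range units. Stain images are background + signal +
noise; quench images share the noise model but not the realization.
Translations are planted as uniform integers in [−max_shift, +max_shift]²
(subpixel optional, off by default, keeping registration oracles exact);
cells are spaced ≥ 2 px apart except for an optional planted fraction of
touching pairs used to exercise boundary separation. Ground truth
(shifts, instance maps, per-cell phenotype and true marker means —
including rule markers outside the imaging panel) is exact.

Not emulated: photobleaching kinetics, tissue autofluorescence texture,
optical PSF, rotation/scale misregistration, cell shape variation beyond
disks, and spatial correlation between phenotype and position. Passing
tests therefore demonstrate the pipeline's correctness and its behavior
under controlled noise — not segmentation performance on real tissue
morphology.

## Numerical choices and degenerate inputs

- ε = 1e−7 clamps log probabilities and smooths Jaccard ratios; the log
  pseudocount is 1e−6.
- A flat image normalizes to all zeros with a warning; a constant marker
  column z-scores to 0 and, under strict `>` comparison, makes all cells
  negative.
- Tiling stride is round(tile·(1 − overlap)); the last tile per axis is
  anchored at dim − tile so coverage is exact, and short axes are
  zero-padded with the valid extent recorded.
- Trial-mean shifts are rounded to the nearest integer before
  application; integer shifts are applied by exact slicing, fractional
  ones (refinement only) by linear interpolation.
- Seeds thread explicitly through every stochastic component (generator,
  crops, training shuffles/augmentation, UMAP).

## Validation problem sizes

The validation module fixes the synthetic study conditions: 50 FOV sets
of 7 cycles at 256² with shifts ≤ 15 px and noise σ = 30 for shift
recovery (and 10 noise-free sets for exactness); ~480 tiles from five
512² FOVs for learnability; 100 random layouts (30% touching) for the
label round trip; five 512² FOVs × 200 cells (≈ 1000 cells) for
profiling fidelity and clustering recovery; 100 random image sizes for
tiling coverage. These sizes are the package's chosen desk-scale
conditions; the same code runs at acquisition scale by changing the
configs.

## Known limitations

- Translation-only registration; rotation or non-rigid deformation is
  out of scope, as is per-FOV independent shift estimation.
- The numpy network trains small models well but is not a GPU framework;
  full-scale schedules (700 epochs on 300² tiles) are impractical on
  one core, though the architecture accepts them.
- The MAD outlier filter and the `mean_minus_3sd` threshold are
  faithful to their definitions but ill-suited to cleanly bimodal
  marker distributions; the guarded-Otsu mode and `mad_k=None` are the
  recommended settings for such data.
- Phenotype precedence is fixed and first-match-wins; probabilistic or
  score-based gating is not implemented.
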