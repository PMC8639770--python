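# Methods

`focusscore` implements both scoring branches of the Bhas 42 cell
transformation assay (CTA) — the hand-crafted-feature/logistic pipeline and
the residual-network classifier — together with the synthetic image
generator that makes them testable and the assay-level promotion decision.
This note records the models, the parameters that matter, and the places
where a convention had to be chosen.

## Synthetic focus images

Assay micrographs are Giemsa-stained monolayers photographed around one
candidate focus. The generator emulates exactly the statistics the
downstream stages consume — color/saturation contrast, region shape and
size — not cytological detail.

A **phenotype** is drawn per image from class- and style-conditional
uniform ranges over: cell count, cell elongation (aspect ratio),
orientation dispersion (deg), stain intensity (0–1), density (cell-area
coverage per unit cluster area; > 1 is the multilayer proxy), border
irregularity (0–1) and cluster radius (px on a 512-px reference canvas,
scaled with the rendered canvas). Defaults at full contrast:

| parameter | positive | negative (base) |
|---|---|---|
| cell count | 140–320 (clamped ≥ 100) | 30–90 |
| elongation | 2.5–4.0 | 1.1–1.7 |
| orientation dispersion | 40–90° | 4–20° |
| stain intensity | 0.60–0.95 | 0.28–0.48 |
| density | 1.4–2.4 | 0.35–0.75 |
| border irregularity | 0.45–0.85 | 0.03–0.25 |
| cluster radius | 110–170 px | 60–110 px |

These encode the assay's six criteria: positives are dark (basophilic),
spindle-shaped, multilayered, randomly oriented, invasive-edged clusters of
≥ 100 cells. Each negative additionally has one randomly chosen criterion
pushed to an unambiguous violation, and the criteria a draw *actually*
fails are recorded per sample, so feature ablations are auditable. Styles
("TPA-like", "micro-focus" for the small dense foci some promoters induce,
"LCA-like" for mainly large dark foci) shift the size/intensity ranges.

**Rendering** (deterministic given seed): a pale low-saturation background
with smoothed noise; a cluster support region bounded by a low-order random
Fourier perturbation of a circle whose amplitude scales with border
irregularity (irregularity 0 is an exact disk — the rendered boundary fits
a circle to < 2 px RMS); a stain wash over the whole support (a focus is a
contiguous mass of cells, and this keeps Otsu segmentation well-posed: the
lightest cell colors have saturation ≈ 0.16 against background ≈ 0.03);
then the individual anti-aliased elliptical cells, alpha-composited with
per-cell color jitter around a Giemsa blue-purple, sized so total cell area
≈ density × support area. Canvas defaults to 512×512 (224×224 minimum,
matching the network input); the resize step makes native size immaterial.

A **contrast dial** interpolates both class distributions toward their
common midpoint: 1 = the study conditions above, 0 = identical
distributions (labels carry no image information), used for null checks.
Note the class-semantics invariants (positives ≥ 100 cells, negatives
violate a criterion) are only guaranteed at full contrast.

What the generator does **not** emulate: optical artifacts, staining
gradients, plate-level context, multiple foci per frame, or the ambiguous
borderline morphologies that make real scoring hard. Perfect synthetic
scores therefore demonstrate pipeline correctness, not expected field
performance on micrographs.

## Segmentation and features

* Saturation is the HSV S channel quantized to 0–255; the discriminant
  (Otsu) threshold maximizes between-class variance over the split
  (≤ t, > t), ties to the lowest bin; a single-valued histogram raises a
  degenerate-image error.
* Foreground is saturation **strictly above** the threshold (the threshold
  bin belongs to the background class of the split). The largest
  8-connected component is the focus region — each micrograph is centred on
  one candidate. Pixels are 0-based row-major.
* `MD` uses Rec. 601 luma rounded to integer. `ED`, `EFP` follow in closed
  form from the pixel-count area. `FRP` uses the weighted
  boundary-configuration perimeter (the common regionprops convention);
  measured error is ≈ 3.5% on a rasterized disk (r = 30) and ≤ 5% on
  axis-aligned squares (side 20–100), which bounds the consequence of the
  estimator choice on `WPD`.
* The `WPD` area weight `(AREA − AREAmin)/(AREAmax − AREAmin)` is clamped
  to [0, 1] for regions outside the training extremes and defined as 0 when
  `AREAmin = AREAmax`. `AREAmin/max` are taken over all training regions
  (positives and negatives).
* An image whose foreground is empty gets a flagged fallback vector
  (MD = whole-image median, ED = WPD = 0) so batch extraction never aborts;
  negatives may legitimately segment to nothing.

## Logistic baseline

Features are standardized (they are on incommensurate scales), then fitted
by maximum likelihood with a tiny ridge (λ = 10⁻⁶ on the standardized
coefficients) that bounds the optimum under complete separation and is
negligible otherwise. The fit is checked in the tests against an
independent BFGS minimization of the penalized negative log-likelihood
(agreement < 10⁻⁴ relative). Decision threshold 0.5, matching the network
branch.

## Residual-network branch

The engine is pure numpy: im2col convolution, batch normalization
(momentum 0.1, eps 10⁻⁵), max pooling, manual backprop (verified against
central differences in float64 to < 10⁻⁴ relative), Adam, and a cosine
learning-rate schedule that starts at the initial rate and reaches the
configured floor (default 0) at the last epoch. The architecture is the
standard 18-layer basic-block residual network with widths (w, 2w, 4w, 8w)
and a single-logit head; w = 64 gives ≈ 11.2 M parameters. `base_width`
scales the width without changing depth or topology.

Protocol defaults (the full study conditions): 224×224 input, 50 epochs,
batch 32, Adam at 10⁻⁴ with cosine annealing, no pretraining
(`pretrained=True` raises — no pretrained weights exist for this engine);
augmentation rotation ±90°, translation ±44 px, shear ±15°, flips p = 0.5.
Checkpoint selection: maximal validation accuracy, earliest epoch on ties.
Trials repeat over seeds (five in the full protocol); metrics are
summarized as mean ± sample SD (n − 1), flagged when n = 1. All
stochastic components (init, shuffling, augmentation) derive from one
master seed per trial, so runs are reproducible to the arithmetic of the
BLAS backend (in practice bit-identical on one machine).

Conventions the protocol leaves open, fixed here: resize precedes
augmentation (±44 px is ≈ 20% of the 224 input, and the configured
translation scales proportionally at other input sizes); out-of-frame fill
is the per-image border-median color (black corners do not occur in
stained micrographs); inputs are scaled to [0, 1] then normalized to
mean 0.5 / SD 0.5 per channel (no pretraining, hence no external
normalization statistics); single logit + sigmoid with binary
cross-entropy rather than 2-class softmax; cosine period = total epochs
with floor 0.

**Scaled-down runs.** The tests and the acceptance script train at 64×64
input, width 16, 10 epochs, batch 16, 160 train / 40 validation / 100 test
images, three seeds — sizes chosen so a full multi-seed experiment runs in
minutes on one CPU. At that scale the full-protocol learning rate of
10⁻⁴ would allow only ~100 Adam steps from random init, far too few to
move the loss, so the scaled configuration uses 10⁻³ — a standard rate for
small from-scratch networks; this is a scaling choice, not a tuned value.
The synthetic task at full contrast is easy by construction, and both
branches reach AUC ≈ 1.0.

**Permuted-label nulls.** Permuting only the *training* labels is not a
valid null for this data: a network trained on noise still emits a random
projection of global image statistics, and because the classes differ
strongly in overall darkness, any random scorer lands far from AUC 0.5
against true test labels (empirically ≈ 0.95 or ≈ 0.05, sign at random —
the logistic baseline shows the same effect). The null experiments
therefore permute the labels of the *entire* dataset, including the
evaluation labels, under which any score function is label-independent and
AUC concentrates at 0.5.

## Evaluation and the promotion rule

Splits are stratified per class: shuffle with the split seed, then
largest-remainder allocation, which keeps every split's class ratio within
one sample of the overall ratio and recovers 70/10/20 exactly on divisible
inputs. Positive prediction is score ≥ threshold (closed on the positive
side); recall is sensitivity on the transformed-focus class. ROC sweeps all
distinct score thresholds; trapezoidal AUC equals the Mann–Whitney
concordance probability with ties counted ½ (verified against brute-force
pairwise counting to 10⁻⁹).

The promotion call takes per-well focus counts by concentration
(≥ 2 wells per group), reports one-way ANOVA and Dunnett many-to-one
p-values versus the vehicle control, and calls the chemical a promoter
when two *adjacent* members of the concentration ladder are both
significant at α (default 0.05). ANOVA gating (Dunnett only consulted if
ANOVA is significant) is available behind a flag; the default reports both
and gates on Dunnett alone. Degenerate plates with zero variance
everywhere are flagged and decided by mean comparison.

Sidedness: the default is the conventional two-sided Dunnett test, but a
one-sided "greater" mode is first-class, because promotion screens for an
*increase* in focus frequency — and on a reconstructed reference-promoter
plate (integer well counts matching published per-concentration
mean ± SD, six wells per group; a synthetic reconstruction, not original
data), only the one-sided test reproduces the published
significant-at-two-consecutive-concentrations promoter call (one-sided
p ≈ 0.037 at the two mid concentrations versus ≈ 0.075 two-sided, with
the group moments pinning the p-values). Dunnett p-values agree with R's
`multcomp` implementation to ~4 decimals.

## Known limitations

* The synthetic classes are far more separable than real focus candidates;
  absolute metric values on synthetic data say nothing about performance
  on real micrographs.
* The numpy engine is CPU-bound; the full 224-px, 50-epoch, width-64
  protocol is supported but slow (hours), and is not exercised by the test
  suite.
* Dunnett p-values use a quasi-random multivariate-t integration (scipy),
  so they reproduce only to ~10⁻⁴ across runs.
* One focus per image is assumed; whole-well scanning and multi-focus
  detection are out of scope, as are staining-chemistry and plate-layout
  effects.
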