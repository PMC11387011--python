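# Methods

## The problem setting

The package targets image-based taxonomic classification of filamentous
fungi cultured from soil. Each isolate is one Petri-dish colony,
photographed in composite group scans (3 × 4 dishes on a blue screen) and
annotated by molecular barcoding with a six-rank path, phylum > class >
order > family > genus > species. The data regime has three defining
difficulties: small n (hundreds of isolates), heavy class imbalance that
propagates down the hierarchy, and downward-closed label missingness
(annotation reaches some rank and fails below it). The pipeline measures
how far down the hierarchy colony morphology supports classification,
and where on the dish a model's evidence comes from.

## Synthetic collections

Because real collections of this kind are not freely redistributable, the
package includes a first-class generator whose defaults encode the study
conditions: 606 isolates; 5 / 11 / 20 / 40 / 80 / 190 taxa per rank;
leaf frequencies proportional to rank⁻¹·⁵ (one knob, `skew`, reproducing
"few dominant taxa, many singletons"); marginal missing-label fractions
11/606 … 319/606 from phylum to species; 3 × 4 group scans on a blue
background; and a 5 % chance of a handwriting-like mark on the agar.

**Missingness model.** Each record draws a single uniform `u`; its label
at rank r is missing iff `u < missing_rates[r]`. With non-decreasing
rates this yields downward-closed missingness by construction and exact
marginal rates in expectation. This mirrors molecular annotation, which
fails from some rank downward.

**Morphology model.** A colony's look is a parameter vector (hue,
saturation, brightness, extension fraction = colony radius / dish radius,
edge roughness, patch density, ring contrast, texture scale). The phylum
fixes the means — phylum hues are evenly spaced on the color wheel with a
guaranteed minimum separation (default half the spacing) — and each
deeper taxon adds a zero-mean perturbation scaled by
`inheritance_decay^depth`. `inheritance_decay` is the package's
separability dial: 0 makes every species of a phylum identical (an oracle
for "signal exists"), 1 keeps full within-phylum variation. The dial is
biologically motivated — hyphal growth speed is phylogenetically
conserved at least at the phylum level — but per-rank morphological
separability has not been quantified for real collections, so no
biological value is asserted; the default 0.3 expresses "phylum-dominant,
weakly heritable below".

**Renderer.** Parametric-geometric, not biophysical: an agar disk with a
darker rim band, a colony disk with a sinusoid-perturbed boundary,
hard-edged interior blob patches, an optional concentric ring, and
Gaussian-correlated fine texture (amplitude 1.5 % of full scale — the
"noise floor" referenced by the flat-colony test). This is sufficient to
encode the characters under study (color, extension rate, patchiness,
rim) while remaining fully deterministic per seed. Handwriting marks are
short dark strokes with per-pixel ink-pressure jitter, confined to a box
that fits inside the agar annulus; a colony occupying the whole dish
leaves no room and the mark is skipped. The generator does not model
hyphal growth dynamics, sporulation, exudation, or scanner optics —
conclusions from passing tests are about the pipeline's mechanics, not
about real fungal plasticity, which is far larger.

## Preprocessing

Dish detection is a gradient-based Circle Hough Transform: Canny edges
(σ = 2), circular voting over a radius range derived from the grid
geometry (dish radius ≈ half the smaller cell side ± 20 %, radius step
1 px), non-maximum suppression at 1.5 × the minimum radius, and an
absolute accumulator threshold of 0.35 so a blank scan yields zero
detections. Detected circles are sorted row-major. Crops take
`2r(1 + margin)` squares with `margin = 0.05` so the dish rim — a region
models demonstrably attend to — stays inside the frame. Resizing uses
pixel area relation implemented exactly: two row-stochastic
fractional-coverage matrices, equal to block averaging for integer
factors.

Missing labels are imputed hierarchically: a missing rank takes
`<nearest-known-ancestor>_<rank>`. Records missing even the phylum root
at `Unknown` (`Unknown_phylum`, `Unknown_class`, …): they have no known
ancestor, and a shared Unknown lineage keeps them usable without
inventing structure. The suffix guarantees imputed names never collide
with real taxa and makes the operation idempotent.

The 70/30 split is stratified at the modelled rank with round-half-up on
the train count and largest-remainder allocation across classes;
singleton classes are forced into training, because a test-only class can
never be predicted and degenerates correlation scoring. K-fold
assignment deals each class's shuffled members to the currently smallest
fold, guaranteeing fold sizes within one of each other (606 → 122 + 4 ×
121) while staying approximately stratified.

## Imbalance treatments

The imbalance profile reports C (categories), MC+ / MC− (majority /
minority counts; a class is "majority" when its count exceeds n/C) and
LRiD, operationalized as the likelihood-ratio (G) statistic against the
uniform distribution, `2 Σ_c n_c ln(n_c C / n)` — zero iff uniform,
monotone under majority-to-minority transfers.

Oversampling balances every training class up to MC+ (classic random
oversampling), strictly after the train/test split and only within the
training partition, so donor and copy are always co-partitioned and the
test set is untouched. Naive copies are randomly flipped and
lighting-shifted (additive, ±0.1 of full scale); augmented copies are
random `crop_side` crops of the donor's `pre_crop_side` rendition
(reference sizes 224 from 356) with brightness/contrast/saturation jitter
(factors in [0.8, 1.2]) and flips. Jitter magnitudes are package
defaults; the balancing rank follows per-classifier loss exposure — each
SL/HC rank model balances at its own rank, ML at species. Every
synthetic image carries provenance (donor index, transform record).

## Models

Three architectures share a pluggable backbone:

* **SL** — one independently trained classifier per rank;
* **ML** — one backbone, six heads, loss = unweighted sum of per-rank
  softmax cross-entropies; per-rank argmaxes may form invalid paths, and
  that inconsistency rate is measured, never forced to zero;
* **HC** — six stacked classifiers C_phylum < … < C_species. The
  operative mechanism of the nested-loss chain is read as parameter
  hand-off: each stage trains on its own rank's cross-entropy and its
  trained backbone initializes the next stage (fresh head). The
  compositional reading — stage r also keeps ranks 0..r−1 in its
  objective — is available as `train_hc(..., joint=True)` but is not the
  default. The hand-off is audited parameter-for-parameter in tests.

The default backbone is a four-block CNN (3×3 convolutions with channels
8/16/32/64, per-channel standardization, ReLU, 2×2 max pooling, global
average pooling), implemented in numpy with explicit backpropagation.
Optimization is SGD with momentum 0.8, L2 weight decay 0.01, learning
rate 0.001, Xavier initialization, softmax cross-entropy, 20 epochs,
batch size 32 — the reference hyperparameters for this task. Those
settings are sized for fine-tuning a large pretrained network, which
trains a small from-scratch CNN too slowly; rather than changing them,
the backbone ends in a fixed ×8 feature gain after pooling, an
architectural choice that restores a usable gradient scale at the same
optimizer settings. A DenseNet-169 transfer-learning backbone is part of
the interface; it requires a locally cached weight bundle and raises an
explicit error naming the cache path when absent (no silent downloads).

Per-epoch histories record train/test accuracy and MCC; the best epoch is
the one maximizing test MCC (earliest on ties), since MCC is the honest
indicator under imbalance.

## Evaluation

Multiclass MCC is the R_K statistic computed from the confusion matrix;
it reduces to the binary TP/TN/FP/FN formula for two classes. A
degenerate denominator (all mass in one row or column) returns 0 — the
standard convention, needed because deep-rank test partitions can be
single-class. Tests verify the implementation against exhaustive small
matrices (binary closed form) and against scikit-learn as an independent
route. Cross-validation retrains from scratch per fold with
fold-specific oversampling, so no augmented copy of a test image ever
enters training.

## Explanation

The local surrogate is authored from scratch. Superpixels come from
quickshift (kernel size 6, max distance 50, ratio 0.5 — the reference
settings; the "ratio" is mapped to quickshift's color/space ratio since
it is listed among segmentation parameters). The neighborhood is 1000
binary designs (each segment kept with probability ½, first row
unperturbed); masked segments take their per-segment mean color — the
standard fill; note that on highly uniform synthetic regions this
perturbation is nearly an identity, so explanations concentrate where
masking actually changes the image. Proximity weights are
`exp(−d²/0.25²)` on cosine distance to the all-ones design; the weighted
least-squares fit carries an intercept and a 1e-8 ridge so duplicated
designs or never-toggled segments stay solvable. The explanation mask is
the union of the top-|weight| segments, at most 100 (`selected
features`), capped at the segment count.

For synthetic dishes the mask is attributed geometrically to colony
interior, colony rim, agar, dish rim, confounder box and background; rim
bands are the outer 10 % of the respective radius. Attribution requires
ground-truth geometry and therefore errors on real-mode records.

## Orchestration and reproducibility

`run_grid` executes the 3 × 3 grid (architectures × treatments), writing
a tidy summary CSV, per-cell histories, figures and a manifest; a failed
cell is logged and skipped without aborting the rest. Every cell's seed
derives from the global seed by stable hashing of the cell name, so
adding cells never shifts existing results; identical config + seed
reproduces outputs bit-for-bit (the numpy implementation has no
nondeterministic kernels).

## Problem sizes used by the test suite

Unit tests run on 30-90 isolates at 32 px. The scientific suites use the
collection-scale conditions at working resolution: the per-rank decline
suite trains the six SL models on 606 isolates at 64 px for 20 epochs;
the overfitting suite uses 250 isolates with full within-phylum variation
(`inheritance_decay = 1`) and skew 2.0 at the species rank; the
confounder suite trains on 100 isolates of two species with identical
morphology (extension fixed at 0.35 so the mark is legible) where the
mark is perfectly label-correlated. These sizes are the package's chosen
desk-scale study conditions.

## Known limitations

* The renderer's within-class variation (render noise, jitter) is far
  smaller than real fungal morphological plasticity; absolute scores on
  synthetic data are optimistic and only orderings/contrasts are
  meaningful.
* The DenseNet-169 path is interface-only without a local weight cache;
  all shipped experiments use the small CNN.
* Real-mode group scans assume the detector finds every dish; undetected
  cells are logged and skipped, and explanation attribution is
  unavailable without ground-truth geometry.
* LRiD is one reasonable operationalization (G-statistic vs uniform) of
  a statistic whose exact published definition is not stated.
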