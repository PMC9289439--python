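# Methods

## Problem setting

`fieldmark` probes genotype x phenotype relationships from overhead crop
imagery. The inputs are (i) a genotype table of diploid biallelic SNP
calls per cultivar, (ii) named *marker families* (groups of related SNPs
treated as one unit), (iii) a plot map assigning each cultivar to a small
number of field plots, and (iv) RGB images of each plot collected several
times per day over a multi-day window. Two pipelines relate the images to
a marker family:

1. **Direct classification** — a CNN is trained end to end to predict
   whether an image shows a homozygous-reference or homozygous-alternate
   cultivar for the family.
2. **Plot-level metric learning** — a CNN is first pre-trained, with no
   marker labels, to identify which field plot an image came from
   (normalized-proxy softmax loss); its frozen global-average-pooled
   (GAP) features then feed k-NN, PCA+RBF-SVM, and fine-tuned linear
   heads for the marker task.

Class activation maps (CAMs) localize the image evidence:
`M_c(x, y) = sum_k w_k^c f_k(x, y)` over the final convolutional block's
feature maps, where `w^c` are the output layer's weights for class `c`.
With a bias-free head, `mean_{x,y} M_c = logit_c` exactly; this identity
is asserted in the tests and is the reason the default head has no bias
and CAMs are never min-max normalized before scoring (overlays normalize
symmetrically for display only; red supports the class, blue detracts).

## Labeling, splitting, sampling

A cultivar is **ALTERNATE** for a family when at least one member SNP is
homozygous-alternate (one polymorphism can already alter the phenotype),
**REFERENCE** only when every member SNP is homozygous-reference, and
**EXCLUDED** otherwise (heterozygous or missing calls without any
homozygous-alternate call). Heterozygous phenotypes are out of scope.

Splits keep train and test cultivars disjoint. The test set takes
`floor(min_class_cultivars / 2)` cultivars per class, then subsamples
images of the larger class so both classes contribute the same number of
test images, protecting at least one image per test cultivar so the
cultivar balance survives the image balance (the split shrinks further
only for pathologically image-poor inputs). A label-blind predictor
therefore scores 50% per image; per cultivar the tie rule (ties go to
REFERENCE) biases reference and alternate cultivars symmetrically, so
50% holds there too. Training batches come from a seeded balanced
sampler: each batch holds `ceil(b/2)` / `floor(b/2)` images of the two
classes, re-sampling the minority class with replacement within an epoch.

Ties are broken deterministically everywhere: exact logit ties and
per-cultivar vote ties resolve to REFERENCE; k-NN distance ties resolve
by ascending image id.

## Network and training

The CNN kernel is implemented in NumPy with explicit forward/backward
passes (3x3 convolutions as nine tap-shifted matrix products in
channels-last layout, 2x2 max pooling, GAP, a linear head; Adam and
SGD-with-momentum optimizers). Everything is seeded and single-threaded
deterministic: identical seeds reproduce loss traces and predictions bit
for bit.

Two design points matter for interpretation:

* **Replicate ("edge") border padding.** Plot-cropped canopy imagery
  continues past the crop; zero padding would manufacture a salient dark
  frame at the image border. Empirically a zero-padded network's CAM
  argmax concentrated on border cells for uninformative models, biasing
  the pointing game; edge padding removes the artifact at its source.
  The backward pass folds pad-ring gradients onto border pixels
  (verified against finite differences).
* **CAM resolution.** The default `small-4block` backbone (channels
  16-32-64-64) pools after the first three blocks only, so on 64 px
  inputs the final block keeps an 8x8 grid. A fully pooled 4x4 grid
  makes the pointing game geometrically unwinnable for compact traits:
  the bilinearly upsampled argmax can sit at most one 16 px cell center
  from the trait, farther than the trait radius.

Preprocessing follows the classification pipeline's conventions: resize
the largest side to the target side, zero-pad the short side square,
random crop + horizontal flip at training time and center crop at eval,
then per-channel normalization by training-set statistics (dataset
statistics, not generic ones, since the backbones are trained from
scratch). Hyperparameter defaults: Adam, learning rate 1e-4, 20 epochs,
100-image balanced batches for classification; SGD with momentum 0.9,
learning rate 0.01 decayed x0.1 every 10 epochs, 25-image batches, at
most 40 epochs for embedding pre-training, stopping early once the
relative epoch-loss improvement stays below 1e-4 for 3 epochs (a
quantified reading of "stop on training-loss convergence").

The proxy loss compares unit-normalized embeddings and proxies by cosine
similarity at temperature 1/9 (a common proxy-softmax scaling; the
choice is configurable and the loss literature supports either dot or
cosine — cosine is used for scale invariance). Proxies initialize from a
seeded normal, normalized.

**Linear-head schedule.** The fine-tuned head on the frozen embedding
uses SGD without momentum at learning rate 0.1 decayed x0.1, as in the
embedding pipeline's conventions, but the decay is counted in optimizer
*steps* (default 1000) rather than epochs: an epoch of a desk-scale
campaign is ~5 steps, so an epoch-counted decay would freeze the head
after ~25 updates, far short of convergence (observed: test accuracy
0.73 against a 0.94 logistic-regression ceiling on the same features).
One thousand steps is what a few epochs represent on a full-scale
campaign with tens of thousands of images, making the schedule
dataset-size invariant. The head trains on class-balanced batches, stops
when training accuracy plateaus (< 0.1 pp change over 20 epochs), and
asserts the backbone is byte-identical before and after.

Heads otherwise: k-NN with k = 11, Euclidean distance on raw GAP
features (metric not otherwise specified; raw features keep the GAP
scale the SVM also sees); PCA to 60 components fitted on training rows
only, centering but not standardizing (PCA's definition), then an RBF
SVM with C = 1 and the 1/(n_features x variance) gamma heuristic —
neither constant tuned. Plot-day features are the double-precision
arithmetic mean of a plot-day's image embeddings, used in both training
and testing for the SVM, with labels inherited from the plot's cultivar.

## Synthetic field campaigns

The generator emulates a gantry campaign over a cultivar panel: `n`
cultivars (default 390) each grown in two plots, ~11 usable images per
plot per day over a month-long window, 512 px plot crops. Tests and the
acceptance script use explicitly smaller layouts (40 cultivars, 2-3
days, 4-11 images per plot-day, 64 px) so each experiment runs in CPU
minutes; the statistical structure, not the scale, is what the
properties exercise.

Rendering: a green canopy of seeded value noise plus random elliptical
leaf strokes; per-plot appearance latents (hue tint, stand density, leaf
scale) persist across a plot's images so plot identity is learnable; an
illumination gain jitter (sigma 0.05) is drawn per image from a stream
independent of genotype. Four genotype-linked trait operators perturb
carrier images with amplitude `effect_size` (beta): textured panicle
blobs (bright speckled discs of radius H/8..H/6 — panicles are large,
textured canopy features), leaf-midrib brightening, global waxy
brightening, and leaf-edge browning. Expression is Bernoulli per image
with probability pi, so a trait can appear in only a subset of a plot's
images. The truth mask records every pixel the operator touches; at
beta = 0 the pixels are untouched but the mask still marks where the
trait *would* render, keeping localization baselines scorable on null
data. Background, trait, and illumination randomness come from separate
seeded streams keyed by (plot, day, image), so with beta = 0 the
class-conditional image distributions are pixel-identical under matched
seeds — the class-blindness control the null experiments rely on.

**Plot signature strength.** `plot_signature` scales the persistent
plot-appearance latents. At the default 1.0 the embedding can identify
plots partly from appearance; at 0.0 plots differ only in what grows in
them, so genotype-linked traits are the sole persistent plot signal —
the closest analog, in a generator without cultivar-level appearance
variation, to a real field where a plot's signature largely *is* its
cultivar's phenotype. The initial latent magnitudes made plot identity
recoverable from a color histogram alone, which no single-species canopy
exhibits; they were reduced once to subtle values on that ground.

What the generator does **not** emulate: real plant morphology and
occlusion, radiometric camera effects, soil/weed background, growth over
time (days differ only by random draws), and cultivar-level appearance
beyond the modeled traits. Passing recovery tests therefore show the
pipelines extract genotype-linked visual signal under controlled
conditions, not that they reach any particular accuracy on real
imagery.

## Benchmark experiments

* **Recovery (direct pipeline).** 40 cultivars x 2 plots x 3 days x 4
  images at 64 px, panicle trait, beta = 1, pi = 1: test accuracy >= 0.9
  per image; the identical pipeline at beta = 0 lands within its 95%
  Wilson CI of 0.5.
* **Recovery (embedding pipeline).** Proxy pre-training on the same
  campaign's 80 plots, then the linear head: >= 0.8 per-image accuracy;
  held-out same-plot pairs are closer in cosine than different-plot
  pairs.
* **Plot-day aggregation.** Campaigns with pi = 0.3, beta = 1, ~11
  images per plot-day and `plot_signature = 0`: the SVM on plot-day
  averaged features beats the per-image SVM on every seed. The
  mechanism requires both partial expression (per-image features cap
  near 0.5 + pi/2) and a plot-day with enough images that some express
  (P >= 1 expressing image = 1 - 0.7^11 ~ 0.98). With a strong
  appearance signature the embedding memorizes plots instead, per-image
  features become effectively plot-level already, and pooling has
  nothing left to average out — the directional effect is a statement
  about the partial-expression regime, not a universal ordering.
* **Localization.** On the strong-effect recovery model, the
  predicted-class CAM's pointing-game hit rate is >= 0.8 and >= 4x the
  random-smooth-map baseline (~ the mask-area fraction); at beta = 0 the
  hit rate is statistically indistinguishable from that baseline
  (two-proportion test, alpha 0.01). IoU uses the top-10% CAM pixels
  (typical sparse-trait footprint in the renderer).

Tie-breaks, seeds, and problem sizes above are the package's defaults
and are restated in the test suite; `scripts/acceptance.py` recomputes
every quantity from scratch at these sizes.

## Known limitations

* The backbones are compact CNNs trained from scratch; transfer from
  generic pretrained features, and the behavior of 2048-d embeddings, is
  out of reach of the desk-scale experiments (the embedding-capacity
  effect matters: narrow embeddings actively discard within-plot
  inconsistent features, which is why the aggregation experiment pins
  the regime it tests).
* Heterozygous cultivars are excluded, never modeled; MISSING calls are
  not imputed; multi-allelic SNPs are unsupported.
* Per-cultivar accuracy requires knowing which test images share a
  cultivar; plot-day accuracy likewise assumes the plot map is correct.
* The pointing game scores only the argmax; a CAM that highlights the
  trait *and* much else can still hit. The IoU@top-q metric partially
  compensates.
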