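# fieldmark

Genotype x phenotype association from overhead crop imagery.

Plant geneticists and breeders often know *that* a genetic marker
matters, but not what it looks like in the field. `fieldmark` probes
this relationship with convolutional networks trained on plot-level
field images of a cultivar panel: given diploid SNP calls per cultivar,
a named family of related SNPs, a plot map, and per-plot-day RGB images,
it

* labels each cultivar **reference** (homozygous-reference for every
  family SNP) or **alternate** (homozygous-alternate for at least one),
  excluding heterozygous/missing cases;
* builds disjoint-cultivar train/test splits whose test sets are
  balanced in both images and cultivars, so chance performance is 50%;
* trains either a **direct classifier** (CNN on reference-vs-alternate,
  class-balanced batches) or a **plot-level metric-learning embedding**
  (normalized-proxy softmax over field plots — no marker labels) with
  k-NN (k = 11), PCA-60 + RBF-SVM, and fine-tuned linear heads on the
  frozen GAP features;
* evaluates per image, per cultivar (mode of image predictions), and
  per plot-day (heads re-run on plot-day averaged features);
* localizes the learned phenotype with **class activation maps**:
  `M_c(x, y) = sum_k w_k^c f_k(x, y)`, whose spatial mean equals the
  class logit exactly for the bias-free head, rendered as red (supports
  the class) / blue (detracts) overlays.

A synthetic field-campaign generator with pixel-level truth masks of the
genotype-controlled trait provides controlled benchmarks: recovery of a
planted effect, null controls at zero effect size, partial per-image
trait expression to exercise plot-day aggregation, and pointing-game /
IoU scoring of CAM localization. See `docs/methods.md` for the model,
assumptions, and what the synthetic results do and do not show.

## Worked example

```python
import fieldmark as fm
from fieldmark.model import MarkerClassificationModel
from fieldmark.classify import ClassifyTrainConfig

config = fm.FieldConfig(
    n_cultivars=40, n_days=3, images_per_plot_day=4, image_size=(64, 64),
    families=(fm.FamilySpec(name="fam_panicle",
                            trait=fm.TraitType.PANICLE_BLOB,
                            effect_size=1.0),),
    expression_prob=1.0, seed=0,
)
dataset = fm.generate_arrays(config)                     # 960 images
model = MarkerClassificationModel.from_dataset(dataset, seed=0)
results = model.fit(ClassifyTrainConfig(epochs=20, batch_size=100, seed=0))
print(results.summary())
```

prints (one CPU, about a minute of training):

```
   Marker classification (direct CNN)
========================================
                           value
----------------------------------------
       train images                  480
        test images                  480
             epochs                   20
   final train loss               0.1038
   test acc (image) 0.985 [0.970, 0.993]
test acc (cultivar) 1.000 [0.839, 1.000]
----------------------------------------
```

The held-out cultivars' genotype is recovered from imagery alone: 98.5%
of test images, and every test cultivar by majority vote. The same
campaign rendered with `effect_size=0.0` yields 0.535 [0.491, 0.580] —
a 95% CI containing chance, confirming nothing but the planted trait
carries label information. `results.cam(image_id)` returns the class
activation map for any test image; on this campaign its argmax lands
inside the true panicle mask for 85% of expressing test images (the
random-smooth-map baseline is 16%).

The embedding pipeline is the `PlotEmbeddingModel` mirror image:
`fit()` pre-trains on plot labels only, and the returned results object
exposes `knn_head`, `svm_head` (per-image or plot-day) and `fc_head`.

A thin CLI covers the same flow from the shell:
`fieldmark generate|split|train-classify|evaluate|cam --help`.

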