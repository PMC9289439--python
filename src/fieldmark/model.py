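"""Model/Results front end for the two pipelines.

Mirrors the fit-then-inspect idiom of statistical modelling packages:
a model object is built from data, ``fit()`` runs the training pipeline
and returns a results object carrying the fitted weights, loss traces,
accuracies with confidence intervals, and a ``summary()`` table.

``MarkerClassificationModel`` is the direct pipeline (train a CNN on
reference/alternate labels for one marker family).
``PlotEmbeddingModel`` is the metric-learning pipeline (plot-identity
pre-training); its results expose the frozen-feature heads (k-NN, PCA+SVM,
fine-tuned linear) and plot-day aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from . import evalviz, heads
from .backbone import Checkpoint
from .classify import (
    ClassifyTrainConfig,
    attach_truth,
    predict_images,
    train_marker_classifier,
)
from .embed import EmbeddingMatrix, EmbedTrainConfig, extract_features, train_embedding
from .genotypes import DatasetSplit, make_split
from .synth import SyntheticDataset


class MarkerClassificationModel:
    """Direct reference-vs-alternate classification for one marker family.

    Parameters
    ----------
    split : DatasetSplit
        Disjoint-cultivar train/test split for the family.
    images : mapping of image id -> HxWx3 array.
    """

    def __init__(self, split: DatasetSplit, images: Mapping[str, np.ndarray]):
        self.split = split
        self.images = images

    @classmethod
    def from_dataset(
        cls, dataset: SyntheticDataset, family: str | None = None, seed: int = 0
    ) -> "MarkerClassificationModel":
        """Build the model from a synthetic campaign: label cultivars under
        the family rule, split with disjoint cultivars, attach images."""
        labels = dataset.labels(family)
        split = make_split(labels, dataset.images_by_cultivar(), seed=seed)
        return cls(split=split, images=dataset.images)

    def fit(
        self, config: ClassifyTrainConfig = ClassifyTrainConfig()
    ) -> "MarkerClassificationResults":
        checkpoint = train_marker_classifier(self.split, self.images, config)
        return MarkerClassificationResults(model=self, checkpoint=checkpoint)


@dataclass
class MarkerClassificationResults:
    """Fitted direct classifier with evaluation and CAM access."""

    model: MarkerClassificationModel
    checkpoint: Checkpoint
    _test_predictions: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def loss_trace(self) -> list[float]:
        return self.checkpoint.loss_trace

    def predict(
        self, images: Mapping[str, np.ndarray] | None = None, keep_forward: bool = False
    ):
        """Predict the test partition (default) or arbitrary images."""
        if images is None:
            ids = list(self.model.split.test["image_id"])
            images = self.model.images
        else:
            ids = list(images)
        df, kept = predict_images(self.checkpoint, images, ids, keep_forward=keep_forward)
        df = attach_truth(df, pd.concat([self.model.split.train, self.model.split.test]))
        return (df, kept) if keep_forward else df

    def test_predictions(self) -> pd.DataFrame:
        if self._test_predictions is None:
            self._test_predictions = self.predict()
        return self._test_predictions

    def accuracy(self, unit: str = "image") -> tuple[float, tuple[float, float]]:
        """Test accuracy with a Wilson 95% CI; unit 'image' or 'cultivar'."""
        preds = self.test_predictions()
        if unit == "image":
            return evalviz.accuracy_per_image(preds)
        if unit == "cultivar":
            return evalviz.accuracy_per_cultivar(preds)
        raise ValueError("unit must be 'image' or 'cultivar'")

    def cam(self, image_id: str, class_id: int | None = None) -> evalviz.CamMap:
        """Class activation map for one test image (predicted class by
        default), upsampled to the image size."""
        df, kept = predict_images(
            self.checkpoint, self.model.images, [image_id], keep_forward=True
        )
        fw = kept[image_id]
        if class_id is None:
            class_id = int(np.argmax(fw.logits[0]))
        w = self.checkpoint.build_network().head.weight.value
        return evalviz.compute_cam(
            fw, class_id, w, out_size=self.model.images[image_id].shape[:2],
            image_id=image_id,
        )

    def summary(self) -> SimpleTable:
        acc_i, ci_i = self.accuracy("image")
        acc_c, ci_c = self.accuracy("cultivar")
        rows = [
            ["train images", f"{len(self.model.split.train)}"],
            ["test images", f"{len(self.model.split.test)}"],
            ["epochs", f"{len(self.loss_trace)}"],
            ["final train loss", f"{self.loss_trace[-1]:.4f}"],
            ["test acc (image)", f"{acc_i:.3f} [{ci_i[0]:.3f}, {ci_i[1]:.3f}]"],
            ["test acc (cultivar)", f"{acc_c:.3f} [{ci_c[0]:.3f}, {ci_c[1]:.3f}]"],
        ]
        return SimpleTable(
            rows,
            headers=["", "value"],
            title="Marker classification (direct CNN)",
        )


class PlotEmbeddingModel:
    """Plot-identity metric learning on plot-labeled images.

    Consumes only plot labels — marker labels are introduced later, by the
    heads trained on the frozen features.
    """

    def __init__(
        self,
        images: Mapping[str, np.ndarray],
        plot_labels: Mapping[str, str],
        meta: pd.DataFrame | None = None,
    ):
        self.images = images
        self.plot_labels = plot_labels
        self.meta = meta

    @classmethod
    def from_dataset(cls, dataset: SyntheticDataset) -> "PlotEmbeddingModel":
        meta = dataset.image_meta()
        return cls(
            images=dataset.images,
            plot_labels=dict(zip(meta.index, meta["plot"])),
            meta=meta,
        )

    def fit(self, config: EmbedTrainConfig = EmbedTrainConfig()) -> "PlotEmbeddingResults":
        checkpoint = train_embedding(self.images, self.plot_labels, config)
        return PlotEmbeddingResults(model=self, checkpoint=checkpoint)


@dataclass
class PlotEmbeddingResults:
    """Fitted embedding network; heads and aggregation hang off this."""

    model: PlotEmbeddingModel
    checkpoint: Checkpoint

    @property
    def loss_trace(self) -> list[float]:
        return self.checkpoint.loss_trace

    def features(
        self, image_ids: Sequence[str] | None = None
    ) -> EmbeddingMatrix:
        ids = list(image_ids) if image_ids is not None else list(self.model.images)
        return extract_features(
            self.checkpoint,
            {i: self.model.images[i] for i in ids},
            meta=self.model.meta,
        )

    def knn_head(
        self, split: DatasetSplit, config: heads.KnnConfig = heads.KnnConfig()
    ) -> pd.DataFrame:
        train_f = self.features(list(split.train["image_id"]))
        test_f = self.features(list(split.test["image_id"]))
        label_of = dict(zip(split.train["image_id"], split.train["label"]))
        labels = [label_of[i] for i in train_f.meta["image_id"]]
        pred = heads.knn_predict(train_f, labels, test_f.rows, config)
        df = pd.DataFrame({"image_id": test_f.meta["image_id"], "predicted": pred})
        return attach_truth(df, split.test)

    def svm_head(
        self,
        split: DatasetSplit,
        config: heads.SvmConfig = heads.SvmConfig(),
        unit: str = "image",
    ) -> pd.DataFrame:
        """RBF-SVM on PCA-reduced features; unit 'image' or 'plotday'
        (plot-day averaged features in both training and testing)."""
        train_f = self.features(list(split.train["image_id"]))
        test_f = self.features(list(split.test["image_id"]))
        if unit == "plotday":
            train_f = heads.plot_day_matrix(heads.aggregate_plot_day(train_f))
            test_f = heads.plot_day_matrix(heads.aggregate_plot_day(test_f))
            cultivar_label = dict(
                zip(
                    pd.concat([split.train, split.test])["cultivar"],
                    pd.concat([split.train, split.test])["label"],
                )
            )
            train_labels = [cultivar_label[c] for c in train_f.meta["cultivar"]]
            true = [cultivar_label[c] for c in test_f.meta["cultivar"]]
        elif unit == "image":
            label_of = dict(zip(split.train["image_id"], split.train["label"]))
            train_labels = [label_of[i] for i in train_f.meta["image_id"]]
            true_of = dict(zip(split.test["image_id"], split.test["label"]))
            true = [true_of[i] for i in test_f.meta["image_id"]]
        else:
            raise ValueError("unit must be 'image' or 'plotday'")
        pred, decision = heads.svm_fit_predict(train_f, train_labels, test_f, config)
        return pd.DataFrame(
            {
                "image_id": test_f.meta["image_id"],
                "predicted": pred,
                "true": true,
                "decision": decision,
            }
        )

    def fc_head(
        self, split: DatasetSplit, config: heads.FcHeadConfig = heads.FcHeadConfig()
    ) -> "MarkerClassificationResults":
        """Fine-tune a linear head on the frozen backbone; returns a results
        object sharing the direct pipeline's evaluation and CAM surface."""
        ckpt = heads.fc_finetune(self.checkpoint, split, self.model.images, config)
        shim = MarkerClassificationModel(split=split, images=self.model.images)
        return MarkerClassificationResults(model=shim, checkpoint=ckpt)

    def summary(self) -> SimpleTable:
        rows = [
            ["images", f"{len(self.model.images)}"],
            ["plots", f"{len(set(self.model.plot_labels.values()))}"],
            ["epochs run", f"{len(self.loss_trace)}"],
            ["final proxy loss", f"{self.loss_trace[-1]:.4f}"],
        ]
        return SimpleTable(
            rows, headers=["", "value"], title="Plot-identity embedding"
        )
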