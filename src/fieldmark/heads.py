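"""Marker prediction from frozen embeddings: k-NN, PCA+SVM, linear head.

All three heads consume the same frozen GAP feature rows. Per-image
features can be pooled into plot-day features (the arithmetic mean of all
embeddings of one plot on one day), which replaces the per-image rows as
SVM/k-NN input in both training and testing; plot-day labels are inherited
from the plot's cultivar.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import pairwise_distances
from sklearn.svm import SVC

from .backbone import Checkpoint
from .embed import EmbeddingMatrix, extract_features
from .genotypes import LABELS, DatasetSplit
from .nn import SGD, Linear, softmax_cross_entropy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KnnConfig:
    """k-nearest-neighbor head; Euclidean metric, majority vote, k = 11."""

    k: int = 11

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be positive")
        if self.k % 2 == 0:
            warnings.warn("even k can produce mode ties (resolved to REFERENCE)")


@dataclass(frozen=True)
class SvmConfig:
    """PCA to ``pca_dim`` components, then an RBF-kernel SVM.

    ``gamma='scale'`` is the 1/(n_features * variance) heuristic; C and
    gamma are not otherwise tuned.
    """

    pca_dim: int = 60
    C: float = 1.0
    gamma: str | float = "scale"

    def __post_init__(self) -> None:
        if self.pca_dim < 1 or self.C <= 0:
            raise ValueError("pca_dim and C must be positive")


@dataclass(frozen=True)
class FcHeadConfig:
    """Fine-tuned 2-output linear head on the frozen embedding network.

    SGD without momentum, learning rate 0.1 decayed by 0.1 every
    ``decay_steps`` optimizer steps (the step count a few epochs represent
    on a full-scale campaign, so the schedule is dataset-size invariant);
    stops when training accuracy moves less than ``conv_tol`` (fraction)
    over ``conv_patience`` epochs, up to ``max_epochs``.
    """

    learning_rate: float = 0.1
    lr_decay: float = 0.1
    decay_steps: int = 1000
    batch_size: int = 100
    max_epochs: int = 400
    conv_tol: float = 0.001
    conv_patience: int = 20
    seed: int = 0


def feature_checksum(matrix: EmbeddingMatrix) -> str:
    """Checksum of the feature rows; the k-NN and SVM heads assert they
    consume identical extractions by comparing these."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(matrix.rows).tobytes())
    h.update(",".join(matrix.meta["image_id"].astype(str)).encode())
    return h.hexdigest()


def knn_predict(
    train: EmbeddingMatrix,
    train_labels: Sequence[str],
    queries: np.ndarray,
    config: KnnConfig = KnnConfig(),
) -> list[str]:
    """Majority label among the k nearest training rows (Euclidean).

    Distance ties break by ascending training image id; vote ties resolve
    to REFERENCE.
    """
    if train.n == 0:
        raise ValueError("empty training set")
    if config.k > train.n:
        raise ValueError(f"k={config.k} exceeds training set size {train.n}")
    queries = np.atleast_2d(queries)
    labels = np.asarray(train_labels)
    id_rank = np.argsort(np.argsort(train.meta["image_id"].astype(str).to_numpy()))
    dists = pairwise_distances(queries, train.rows, metric="euclidean")
    out = []
    for row in dists:
        order = np.lexsort((id_rank, row))[: config.k]
        votes = (labels[order] == "ALTERNATE").sum()
        out.append("ALTERNATE" if votes > config.k / 2 else "REFERENCE")
    return out


def svm_fit_predict(
    train: EmbeddingMatrix,
    train_labels: Sequence[str],
    test: EmbeddingMatrix,
    config: SvmConfig = SvmConfig(),
) -> tuple[list[str], np.ndarray]:
    """PCA (fit on train only) + RBF SVM; returns (labels, decision values).

    ``pca_dim`` is reduced automatically (with a warning) when it exceeds
    what the training rows can support.
    """
    max_dim = min(train.n, train.dim)
    dim = config.pca_dim
    if dim > max_dim:
        warnings.warn(
            f"pca_dim {dim} exceeds train rank bound {max_dim}; reducing"
        )
        dim = max_dim
    pca = PCA(n_components=dim, svd_solver="full")
    z_train = pca.fit_transform(train.rows)
    z_test = pca.transform(test.rows)
    y = (np.asarray(train_labels) == "ALTERNATE").astype(int)
    svm = SVC(kernel="rbf", C=config.C, gamma=config.gamma)
    svm.fit(z_train, y)
    decision = svm.decision_function(z_test)
    pred = svm.predict(z_test)
    return [LABELS[i] for i in pred], decision


def aggregate_plot_day(features: EmbeddingMatrix) -> pd.DataFrame:
    """Average all image embeddings of each (plot, day) into one feature.

    Returns a frame with columns plot, day, n_images, vector (float64
    mean); cultivar is carried through when present in the metadata.
    """
    meta = features.meta
    if "plot" not in meta.columns or "day" not in meta.columns:
        raise ValueError("plot-day aggregation needs plot and day metadata")
    rows = []
    df = meta.copy()
    df["_row"] = np.arange(len(df))
    for (plot, day), group in df.groupby(["plot", "day"], sort=True):
        idx = group["_row"].to_numpy()
        vec = features.rows[idx].astype(np.float64).sum(axis=0) / len(idx)
        row = {"plot": plot, "day": day, "n_images": len(idx), "vector": vec}
        if "cultivar" in group.columns:
            row["cultivar"] = group["cultivar"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def plot_day_matrix(agg: pd.DataFrame) -> EmbeddingMatrix:
    """Repackage aggregated plot-day rows as an EmbeddingMatrix whose
    'image id' is the plot-day unit id."""
    rows = np.stack(agg["vector"].to_numpy())
    meta = pd.DataFrame(
        {
            "image_id": [f"{p}@d{d}" for p, d in zip(agg["plot"], agg["day"])],
            "plot": agg["plot"].to_numpy(),
            "day": agg["day"].to_numpy(),
        }
    )
    if "cultivar" in agg.columns:
        meta["cultivar"] = agg["cultivar"].to_numpy()
    return EmbeddingMatrix(rows=rows, meta=meta)


def fc_finetune(
    embed_checkpoint: Checkpoint,
    split: DatasetSplit,
    images: Mapping[str, np.ndarray],
    config: FcHeadConfig = FcHeadConfig(),
) -> Checkpoint:
    """Train a fresh 2-output linear head on the frozen embedding network.

    Backbone weights are byte-identical before and after (asserted); only
    the new head layer learns, on the split's training images and marker
    labels. Returns a classifier checkpoint (frozen backbone + new head)
    usable for prediction and CAM computation.
    """
    backbone_before = {
        k: v.copy() for k, v in embed_checkpoint.state.items()
    }
    train_ids = sorted(split.train["image_id"])
    feats = extract_features(
        embed_checkpoint, {i: images[i] for i in train_ids}
    )
    label_of = dict(zip(split.train["image_id"], split.train["label"]))
    row_of = {iid: j for j, iid in enumerate(feats.meta["image_id"])}
    y = np.array(
        [LABELS.index(label_of[i]) for i in feats.meta["image_id"]]
    )
    x = feats.rows.astype(np.float32)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 303)))
    head = Linear(x.shape[1], 2, rng, bias=False)
    opt = SGD(head.params, lr=config.learning_rate, momentum=0.0)
    acc_trace: list[float] = []
    from .genotypes import plan_balanced_batches  # balanced sampler, as in training

    step = 0
    for epoch in range(config.max_epochs):
        plan = plan_balanced_batches(
            split.train, config.batch_size, seed=(config.seed * 1013 + epoch) % 2**31
        )
        for batch in plan.batches:
            opt.lr = config.learning_rate * config.lr_decay ** (step // config.decay_steps)
            idx = np.array([row_of[i] for i in batch])
            logits = head.forward(x[idx])
            _, dlogits = softmax_cross_entropy(logits.astype(np.float64), y[idx])
            opt.zero_grad()
            head.backward(dlogits)
            opt.step()
            step += 1
        train_acc = float(
            np.mean(np.argmax(head.forward(x), axis=1) == y)
        )
        acc_trace.append(train_acc)
        k = config.conv_patience
        if len(acc_trace) > k and abs(acc_trace[-1] - acc_trace[-1 - k]) < config.conv_tol:
            logger.info("fc head accuracy converged at epoch %d", epoch + 1)
            break
    # freeze contract: the embedding backbone must be untouched
    for key, before in backbone_before.items():
        if not np.array_equal(embed_checkpoint.state[key], before):
            raise AssertionError("frozen backbone weights were modified")
    n_backbone = len(embed_checkpoint.state) - len(
        embed_checkpoint.build_network().head.params
    )
    state = {
        f"param_{i}": embed_checkpoint.state[f"param_{i}"].copy()
        for i in range(n_backbone)
    }
    state[f"param_{n_backbone}"] = head.weight.value.copy()
    return Checkpoint(
        model_spec=embed_checkpoint.model_spec,
        preprocess_spec=embed_checkpoint.preprocess_spec,
        state=state,
        seed=config.seed,
        config={
            "pipeline": "embedding+fc",
            "epochs_run": len(acc_trace),
            "final_train_accuracy": acc_trace[-1] if acc_trace else None,
        },
        loss_trace=acc_trace,
    )
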