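"""Pipeline 1: train a CNN end-to-end to predict reference vs. alternate.

The network sees class-balanced batches drawn from the training partition
of a disjoint-cultivar split, with random horizontal flips and per-channel
normalization by training-set statistics, and is optimized with Adam. Class
order is fixed: output 0 = REFERENCE, output 1 = ALTERNATE; exact logit
ties resolve to REFERENCE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .backbone import (
    Checkpoint,
    ForwardResult,
    ModelSpec,
    Network,
    PreprocessSpec,
    compute_channel_stats,
    preprocess_batch,
)
from .genotypes import LABELS, DatasetSplit, plan_balanced_batches
from .nn import Adam, softmax_cross_entropy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifyTrainConfig:
    """Hyperparameters for the direct classification pipeline.

    Defaults: Adam with learning rate 1e-4, 20 epochs, 100-image balanced
    batches, random horizontal flips; no validation split or early stopping
    (a fixed epoch budget).
    """

    learning_rate: float = 1e-4
    epochs: int = 20
    batch_size: int = 100
    seed: int = 0
    backbone_id: str = "small-4block"
    head_bias: bool = False
    target_side: int | None = None  # default: native side of the input images

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 2:
            raise ValueError("hyperparameters must be positive (batch_size >= 2)")


def _resolve_target_side(
    images: Mapping[str, np.ndarray], ids: Sequence[str], requested: int | None
) -> int:
    if requested is not None:
        return requested
    sides = {max(images[i].shape[:2]) for i in ids}
    if len(sides) != 1:
        raise ValueError(
            "images have mixed sizes; set target_side explicitly"
        )
    return sides.pop()


def train_marker_classifier(
    split: DatasetSplit,
    images: Mapping[str, np.ndarray],
    config: ClassifyTrainConfig = ClassifyTrainConfig(),
) -> Checkpoint:
    """Train the full network on one marker family's split.

    All backbone and head weights are updated. Batches come from the
    balanced batch planner (per-batch class imbalance at most one image);
    the per-epoch mean loss is recorded in the checkpoint's ``loss_trace``.
    Fully deterministic for a fixed seed.
    """
    present = set(split.train["label"])
    if len(present) < 2:
        raise ValueError(f"training set has a single class: {present}")
    train_ids = list(split.train["image_id"])
    means, stds = compute_channel_stats(images[i] for i in train_ids)
    side = _resolve_target_side(images, train_ids, config.target_side)
    pp_train = PreprocessSpec(
        channel_means=tuple(means), channel_stds=tuple(stds),
        target_side=side, mode="train",
    )
    spec = ModelSpec(
        backbone_id=config.backbone_id, n_outputs=2, head_bias=config.head_bias
    )
    net = Network(spec, seed=config.seed)
    opt = Adam(net.params, lr=config.learning_rate)
    label_of = dict(zip(split.train["image_id"], split.train["label"]))
    label_idx = {name: i for i, name in enumerate(LABELS)}
    loss_trace: list[float] = []
    for epoch in range(config.epochs):
        plan = plan_balanced_batches(
            split.train, config.batch_size, seed=(config.seed * 1009 + epoch) % 2**31
        )
        aug_rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, 11, epoch))
        )
        batch_losses = []
        for batch in plan.batches:
            x = preprocess_batch([images[i] for i in batch], pp_train, aug_rng)
            y = np.array([label_idx[label_of[i]] for i in batch])
            result = net.forward(x)
            loss, dlogits = softmax_cross_entropy(result.logits, y)
            opt.zero_grad()
            net.backward_from_logits(result, dlogits)
            opt.step()
            batch_losses.append(loss)
        loss_trace.append(float(np.mean(batch_losses)))
        logger.info("epoch %d/%d loss %.4f", epoch + 1, config.epochs, loss_trace[-1])
    return Checkpoint(
        model_spec=spec,
        preprocess_spec=pp_train.with_mode("eval"),
        state={k: v.copy() for k, v in net.state_dict().items()},
        seed=config.seed,
        config={
            "pipeline": "classification",
            "learning_rate": config.learning_rate,
            "epochs": config.epochs,
            "batch_size": config.batch_size,
        },
        loss_trace=loss_trace,
    )


def predict_image(
    checkpoint: Checkpoint, image: np.ndarray
) -> tuple[str, np.ndarray, ForwardResult]:
    """Predict one image: (label, logits, ForwardResult kept for CAM)."""
    df, results = predict_images(checkpoint, {"_": image}, ["_"], keep_forward=True)
    row = df.iloc[0]
    return row["predicted"], np.array([row["logit_ref"], row["logit_alt"]]), results["_"]


def predict_images(
    checkpoint: Checkpoint,
    images: Mapping[str, np.ndarray],
    image_ids: Sequence[str] | None = None,
    batch_size: int = 128,
    keep_forward: bool = False,
) -> tuple[pd.DataFrame, dict[str, ForwardResult]]:
    """Batched EVAL-mode prediction.

    Returns a predictions frame (image_id, predicted, logit_ref, logit_alt)
    and, when ``keep_forward``, a per-image ForwardResult map for CAM
    computation. Predictions are independent of batch composition (no
    cross-image operations at eval time).
    """
    ids = list(image_ids) if image_ids is not None else list(images)
    net = checkpoint.build_network()
    pp = checkpoint.preprocess_spec.with_mode("eval")
    rows = []
    kept: dict[str, ForwardResult] = {}
    for start in range(0, len(ids), batch_size):
        chunk = ids[start : start + batch_size]
        x = preprocess_batch([images[i] for i in chunk], pp)
        result = net.forward(x)
        pred_idx = np.argmax(result.logits, axis=1)  # ties -> REFERENCE (index 0)
        for j, iid in enumerate(chunk):
            rows.append(
                {
                    "image_id": iid,
                    "predicted": LABELS[pred_idx[j]],
                    "logit_ref": result.logits[j, 0],
                    "logit_alt": result.logits[j, 1],
                }
            )
            if keep_forward:
                kept[iid] = ForwardResult(
                    feature_maps=result.feature_maps[j : j + 1],
                    gap_vector=result.gap_vector[j : j + 1],
                    logits=result.logits[j : j + 1],
                )
    return pd.DataFrame(rows), kept


def attach_truth(predictions: pd.DataFrame, split_part: pd.DataFrame) -> pd.DataFrame:
    """Join predictions with the split's true labels and cultivar ids."""
    truth = split_part.set_index("image_id")[["cultivar", "label"]]
    out = predictions.set_index("image_id").join(truth, how="inner").reset_index()
    return out.rename(columns={"label": "true"})
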