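"""Pipeline 2 pre-training: plot-level metric learning with a proxy loss.

The backbone is trained to tell apart the field plots an image came from:
each plot owns a learnable proxy vector, and an image embedding (the GAP
output) is classified against all proxies by temperature-scaled cosine
similarity with softmax cross-entropy. Marker labels are never consumed —
the function signature only accepts plot labels, so label-blindness holds
by construction. After pre-training the backbone is frozen and its GAP
output serves as a generic image feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .backbone import (
    Checkpoint,
    ModelSpec,
    Network,
    PreprocessSpec,
    compute_channel_stats,
    preprocess_batch,
)
from .nn import SGD, Param, proxy_loss_grad

logger = logging.getLogger(__name__)


@dataclass
class ProxyBank:
    """One learnable unit-direction proxy per field plot."""

    proxies: Param
    plot_ids: tuple[str, ...]
    temperature: float

    @classmethod
    def init(
        cls, plot_ids: Sequence[str], dim: int, temperature: float, seed: int
    ) -> "ProxyBank":
        rng = np.random.default_rng(np.random.SeedSequence((seed, 202)))
        p = rng.standard_normal((len(plot_ids), dim)).astype(np.float32)
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        return cls(proxies=Param(p), plot_ids=tuple(plot_ids), temperature=temperature)

    def index_of(self, plot: str) -> int:
        try:
            return self._index[plot]
        except AttributeError:
            self._index = {p: i for i, p in enumerate(self.plot_ids)}
            return self._index[plot]


@dataclass(frozen=True)
class EmbedTrainConfig:
    """Hyperparameters for the plot-classification pre-training.

    Defaults: 25-image batches, SGD with momentum 0.9, learning rate 0.01
    decayed by 0.1 every 10 epochs, at most 40 epochs with early stopping on
    training-loss convergence (relative improvement < ``conv_tol`` over
    ``conv_patience`` consecutive epochs).
    """

    batch_size: int = 25
    learning_rate: float = 0.01
    momentum: float = 0.9
    lr_decay: float = 0.1
    decay_every: int = 10
    epochs: int = 40
    temperature: float = 1.0 / 9.0
    seed: int = 0
    backbone_id: str = "small-4block"
    conv_tol: float = 1e-4
    conv_patience: int = 3
    target_side: int | None = None

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs, self.decay_every) < 1:
            raise ValueError("batch_size, epochs, decay_every must be positive")
        if self.learning_rate <= 0 or self.temperature <= 0:
            raise ValueError("learning_rate and temperature must be positive")


@dataclass
class EmbeddingMatrix:
    """n x d frozen GAP features with per-row image metadata."""

    rows: np.ndarray
    meta: pd.DataFrame  # columns: image_id (+ plot, day, cultivar when known)

    def __post_init__(self) -> None:
        if self.rows.shape[0] != len(self.meta):
            raise ValueError("one metadata row per feature row required")

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    @property
    def dim(self) -> int:
        return self.rows.shape[1]

    def save(self, features_path: str, meta_path: str) -> None:
        np.save(features_path, self.rows)
        self.meta.to_csv(meta_path, index=False)


def train_embedding(
    images: Mapping[str, np.ndarray],
    plot_labels: Mapping[str, str],
    config: EmbedTrainConfig = EmbedTrainConfig(),
) -> Checkpoint:
    """Pre-train the backbone on the plot-identification task.

    ``plot_labels`` maps image id -> plot id; this is the only supervision.
    Stops early once the epoch training loss has converged. The proxy bank
    is stored in the checkpoint extras (it is discarded at feature-
    extraction time, mirroring the removal of the plot classification
    layer).
    """
    ids = sorted(plot_labels)
    plots = sorted(set(plot_labels.values()))
    if len(plots) < 2:
        raise ValueError("plot pre-training needs at least 2 distinct plots")
    means, stds = compute_channel_stats(images[i] for i in ids)
    sides = {max(images[i].shape[:2]) for i in ids}
    side = config.target_side or (sides.pop() if len(sides) == 1 else None)
    if side is None:
        raise ValueError("images have mixed sizes; set target_side explicitly")
    pp_train = PreprocessSpec(
        channel_means=tuple(means), channel_stds=tuple(stds),
        target_side=side, mode="train",
    )
    spec = ModelSpec(backbone_id=config.backbone_id, n_outputs=2, head_bias=False)
    net = Network(spec, seed=config.seed)
    bank = ProxyBank.init(plots, spec.feature_dim, config.temperature, config.seed)
    params = net.backbone_params + [bank.proxies]
    opt = SGD(params, lr=config.learning_rate, momentum=config.momentum)
    plot_idx = {p: i for i, p in enumerate(plots)}
    y_of = {i: plot_idx[plot_labels[i]] for i in ids}
    loss_trace: list[float] = []
    for epoch in range(config.epochs):
        opt.lr = config.learning_rate * config.lr_decay ** (epoch // config.decay_every)
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 21, epoch)))
        order = rng.permutation(len(ids))
        batch_losses = []
        for start in range(0, len(ids), config.batch_size):
            chunk = [ids[k] for k in order[start : start + config.batch_size]]
            x = preprocess_batch([images[i] for i in chunk], pp_train, rng)
            y = np.array([y_of[i] for i in chunk])
            result = net.forward(x)
            loss, de, dp = proxy_loss_grad(
                result.gap_vector, y, bank.proxies.value, bank.temperature
            )
            opt.zero_grad()
            bank.proxies.grad += dp.astype(np.float32)
            net.backward_from_gap(result, de)
            opt.step()
            batch_losses.append(loss)
        loss_trace.append(float(np.mean(batch_losses)))
        logger.info("embed epoch %d loss %.4f", epoch + 1, loss_trace[-1])
        k = config.conv_patience
        if len(loss_trace) > k:
            prev, cur = loss_trace[-k - 1], loss_trace[-1]
            if (prev - cur) / max(abs(prev), 1e-12) < config.conv_tol:
                logger.info("training loss converged at epoch %d", epoch + 1)
                break
    return Checkpoint(
        model_spec=spec,
        preprocess_spec=pp_train.with_mode("eval"),
        state={k: v.copy() for k, v in net.state_dict().items()},
        seed=config.seed,
        config={
            "pipeline": "embedding",
            "n_plots": len(plots),
            "temperature": config.temperature,
            "batch_size": config.batch_size,
        },
        loss_trace=loss_trace,
        extras={"proxies": bank.proxies.value.copy()},
    )


def extract_features(
    checkpoint: Checkpoint,
    images: Mapping[str, np.ndarray],
    meta: pd.DataFrame | None = None,
    batch_size: int = 256,
) -> EmbeddingMatrix:
    """Frozen GAP features for a set of images (EVAL preprocessing).

    ``meta``, when given, is indexed by image id and contributes plot, day
    and cultivar columns to the row metadata. Backbone weights are read,
    never written.
    """
    ids = sorted(images)
    net = checkpoint.build_network()
    pp = checkpoint.preprocess_spec.with_mode("eval")
    rows = []
    for start in range(0, len(ids), batch_size):
        chunk = ids[start : start + batch_size]
        x = preprocess_batch([images[i] for i in chunk], pp)
        result = net.forward(x)
        rows.append(result.gap_vector)
    features = np.concatenate(rows, axis=0) if rows else np.empty((0, 0))
    meta_df = pd.DataFrame({"image_id": ids})
    if meta is not None:
        for col in ("plot", "day", "cultivar"):
            if col in meta.columns:
                meta_df[col] = meta[col].reindex(ids).to_numpy()
    return EmbeddingMatrix(rows=features, meta=meta_df)
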