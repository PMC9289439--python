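"""Shared CNN contract: preprocessing, backbone, GAP, linear head.

Every network used by the pipelines ends in a final convolutional block
producing ``d`` feature maps, a global average pooling (GAP) layer, and a
linear output head. The forward pass exposes all three stages so that the
class-activation machinery can decompose a logit over space: with a
bias-free head, the spatial mean of the weighted feature-map sum equals the
logit exactly.

Two compact backbones are registered; both are small enough to train on a
CPU in minutes on the synthetic imagery:

* ``small-4block`` — four conv(3x3)/ReLU/maxpool blocks, channels
  16-32-64-64, d = 64 (the default).
* ``tiny-2block`` — two blocks, d = 16 (fast variant for contract tests).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.transform import resize

from .nn import Conv2d, GlobalAvgPool, Linear, MaxPool2, Param, ReLU

# per architecture: (channels per block, pool-after-block flags). The last
# block of the default backbone keeps its resolution so the class-activation
# grid stays fine enough to localize compact traits.
_ARCHITECTURES: dict[str, tuple[tuple[int, ...], tuple[bool, ...]]] = {
    "small-4block": ((16, 32, 64, 64), (True, True, True, False)),
    "wide-4block": ((16, 32, 64, 256), (True, True, True, False)),
    "tiny-2block": ((16, 16), (True, True)),
}


@dataclass(frozen=True)
class PreprocessSpec:
    """Normalization and crop policy shared by training and evaluation.

    Images are resized so their largest side equals ``target_side``
    (preserving aspect ratio), zero-padded on the short side to a square,
    cropped (random position + horizontal flip in TRAIN mode, center crop in
    EVAL mode), and normalized per channel with the training-set statistics.
    """

    channel_means: tuple[float, float, float]
    channel_stds: tuple[float, float, float]
    target_side: int
    mode: str = "eval"  # "train" or "eval"

    def __post_init__(self) -> None:
        if self.mode not in ("train", "eval"):
            raise ValueError("mode must be 'train' or 'eval'")
        if any(s <= 0 for s in self.channel_stds):
            raise ValueError("channel stds must be positive")
        if self.target_side < 16:
            raise ValueError("target_side below minimum backbone input (16)")

    def with_mode(self, mode: str) -> "PreprocessSpec":
        return dataclasses.replace(self, mode=mode)


@dataclass(frozen=True)
class ModelSpec:
    """Backbone identity and head geometry."""

    backbone_id: str = "small-4block"
    n_outputs: int = 2
    head_bias: bool = False

    def __post_init__(self) -> None:
        if self.backbone_id not in _ARCHITECTURES:
            raise ValueError(
                f"unknown backbone {self.backbone_id!r}; "
                f"available: {sorted(_ARCHITECTURES)}"
            )
        if self.n_outputs < 2:
            raise ValueError("n_outputs must be >= 2")

    @property
    def feature_dim(self) -> int:
        return _ARCHITECTURES[self.backbone_id][0][-1]

    @property
    def n_blocks(self) -> int:
        return len(_ARCHITECTURES[self.backbone_id][0])

    @property
    def stride(self) -> int:
        return 2 ** sum(_ARCHITECTURES[self.backbone_id][1])


@dataclass
class ForwardResult:
    """Feature maps f_k(x, y), their GAP vector, and the head logits.

    Batched: ``feature_maps`` is (N, d, H', W'), ``gap_vector`` (N, d),
    ``logits`` (N, n_outputs). GAP and logits are accumulated in double
    precision so the linear decomposition identities hold tightly.
    """

    feature_maps: np.ndarray
    gap_vector: np.ndarray
    logits: np.ndarray


def compute_channel_stats(
    images: Iterable[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std over all pixels of all images (0..1 scale).

    Stds are floored at 1e-6. Order-invariant by construction (moment
    accumulation).
    """
    total = np.zeros(3)
    total_sq = np.zeros(3)
    n_pix = 0
    for img in images:
        x = _to_float01(img)
        total += x.sum(axis=(0, 1))
        total_sq += (x.astype(np.float64) ** 2).sum(axis=(0, 1))
        n_pix += x.shape[0] * x.shape[1]
    if n_pix == 0:
        raise ValueError("channel statistics need at least one image")
    means = total / n_pix
    var = np.maximum(total_sq / n_pix - means**2, 0.0)
    stds = np.maximum(np.sqrt(var), 1e-6)
    return means, stds


def _to_float01(img: np.ndarray) -> np.ndarray:
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {img.shape}")
    if img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError("degenerate zero-area image")
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    return img.astype(np.float64)


def preprocess(
    image: np.ndarray,
    spec: PreprocessSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Resize/pad/crop/flip/normalize one image to a (3, S, S) tensor."""
    x = _to_float01(image)
    s = spec.target_side
    h, w = x.shape[:2]
    if max(h, w) != s:
        scale = s / max(h, w)
        nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
        x = resize(x, (nh, nw), order=1, mode="reflect", anti_aliasing=scale < 1.0)
        h, w = nh, nw
    if h < s or w < s:
        pad_h, pad_w = s - h, s - w
        x = np.pad(x, ((0, pad_h), (0, pad_w), (0, 0)))
        h, w = s, s
    if spec.mode == "train":
        if rng is None:
            raise ValueError("TRAIN preprocessing requires a seeded rng")
        top = int(rng.integers(0, h - s + 1))
        left = int(rng.integers(0, w - s + 1))
        x = x[top : top + s, left : left + s]
        if rng.random() < 0.5:
            x = x[:, ::-1]
    else:
        top, left = (h - s) // 2, (w - s) // 2
        x = x[top : top + s, left : left + s]
    x = (x - np.asarray(spec.channel_means)) / np.asarray(spec.channel_stds)
    return np.ascontiguousarray(x, dtype=np.float32)


def preprocess_batch(
    images: Sequence[np.ndarray],
    spec: PreprocessSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Stacked preprocessing to (N, S, S, 3); fast path when all inputs are
    already square at the target side (the common case for the synthetic
    imagery)."""
    s = spec.target_side
    if all(img.shape[:2] == (s, s) for img in images):
        x = np.stack([_to_float01(img) for img in images])
        if spec.mode == "train":
            if rng is None:
                raise ValueError("TRAIN preprocessing requires a seeded rng")
            flips = rng.random(len(images)) < 0.5
            x[flips] = x[flips, :, ::-1]
        x = (x - np.asarray(spec.channel_means)) / np.asarray(spec.channel_stds)
        return np.ascontiguousarray(x, dtype=np.float32)
    return np.stack([preprocess(img, spec, rng) for img in images])


class Network:
    """Conv backbone + GAP + linear head, per :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, seed: int):
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence((seed, 101)))
        self.layers: list = []
        c_in = 3
        channels, pools = _ARCHITECTURES[spec.backbone_id]
        for i, (c_out, pool) in enumerate(zip(channels, pools)):
            self.layers += [Conv2d(c_in, c_out, rng, first=(i == 0)), ReLU()]
            if pool:
                self.layers.append(MaxPool2())
            c_in = c_out
        self.gap = GlobalAvgPool()
        self.head = Linear(spec.feature_dim, spec.n_outputs, rng, bias=spec.head_bias)
        self.seed = seed

    # -- parameters --------------------------------------------------------
    @property
    def backbone_params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def params(self) -> list[Param]:
        return self.backbone_params + self.head.params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.value for i, p in enumerate(self.params)}

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params):
            arr = np.asarray(state[f"param_{i}"])
            if arr.shape != p.value.shape:
                raise ValueError("checkpoint/state shape mismatch")
            p.value = arr.astype(p.value.dtype)

    # -- passes ------------------------------------------------------------
    def forward_features(self, x: np.ndarray) -> np.ndarray:
        """(N, H, W, 3) tensor -> channels-last feature maps (N, H', W', d)."""
        if x.ndim != 4 or x.shape[3] != 3:
            raise ValueError(f"expected (N, H, W, 3) tensor, got {x.shape}")
        stride = self.spec.stride
        if x.shape[1] % stride or x.shape[2] % stride:
            raise ValueError(
                f"input sides {x.shape[1:3]} not divisible by {stride} "
                f"(backbone stride)"
            )
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def forward(self, x: np.ndarray) -> ForwardResult:
        maps = self.forward_features(x)
        gap = maps.mean(axis=(1, 2), dtype=np.float64)
        logits = gap @ self.head.weight.value.T.astype(np.float64)
        if self.head.bias is not None:
            logits = logits + self.head.bias.value.astype(np.float64)
        return ForwardResult(
            feature_maps=maps.transpose(0, 3, 1, 2),  # expose as (N, d, H', W')
            gap_vector=gap,
            logits=logits,
        )

    def backward_from_logits(self, result: ForwardResult, dlogits: np.ndarray) -> None:
        """Backprop a logit gradient through head, GAP, and backbone."""
        x32 = result.gap_vector.astype(np.float32)
        self.head._x = x32  # reuse Linear backward with the cached GAP input
        dgap = self.head.backward(dlogits.astype(np.float32))
        self.backward_from_gap(result, dgap)

    def backward_from_gap(self, result: ForwardResult, dgap: np.ndarray) -> None:
        """Backprop a GAP-vector gradient through the backbone."""
        n, d, h, w = result.feature_maps.shape
        dmaps = np.broadcast_to(
            dgap.astype(np.float32)[:, None, None, :] / (h * w), (n, h, w, d)
        ).astype(np.float32)
        for layer in reversed(self.layers):
            dmaps = layer.backward(dmaps)


def forward(network: Network, tensor: np.ndarray) -> ForwardResult:
    """Functional forward pass (see :meth:`Network.forward`)."""
    return network.forward(tensor)


@dataclass
class Checkpoint:
    """Trained weights + the specs and seeds needed to reproduce them."""

    model_spec: ModelSpec
    preprocess_spec: PreprocessSpec
    state: dict[str, np.ndarray]
    seed: int
    config: dict = field(default_factory=dict)
    loss_trace: list[float] = field(default_factory=list)
    extras: dict[str, np.ndarray] = field(default_factory=dict)

    def build_network(self) -> Network:
        net = Network(self.model_spec, seed=self.seed)
        net.load_state_dict(self.state)
        return net

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = dict(self.state)
        arrays.update({f"extra_{k}": v for k, v in self.extras.items()})
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "model_spec": dataclasses.asdict(self.model_spec),
            "preprocess_spec": dataclasses.asdict(self.preprocess_spec),
            "seed": self.seed,
            "config": self.config,
            "loss_trace": self.loss_trace,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        try:
            sidecar = json.loads(path.with_suffix(".json").read_text())
            with np.load(path.with_suffix(".npz")) as data:
                arrays = {k: data[k] for k in data.files}
        except (OSError, ValueError, KeyError, json.JSONDecodeError) as exc:
            raise IOError(f"corrupt or missing checkpoint at {path}: {exc}") from exc
        state = {k: v for k, v in arrays.items() if k.startswith("param_")}
        extras = {k[6:]: v for k, v in arrays.items() if k.startswith("extra_")}
        ps = sidecar["preprocess_spec"]
        ps["channel_means"] = tuple(ps["channel_means"])
        ps["channel_stds"] = tuple(ps["channel_stds"])
        return cls(
            model_spec=ModelSpec(**sidecar["model_spec"]),
            preprocess_spec=PreprocessSpec(**ps),
            state=state,
            seed=sidecar["seed"],
            config=sidecar["config"],
            loss_trace=sidecar["loss_trace"],
            extras=extras,
        )
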