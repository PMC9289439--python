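"""Evaluation and visualization: accuracies, CAMs, overlays, localization.

Accuracy is reported per image (fraction of test images correct), per
cultivar (mode of a cultivar's image predictions), and per plot-day
(predictions on pooled plot-day features). Class Activation Maps decompose
a logit over space: ``M_c(x, y) = sum_k w_k^c f_k(x, y)``, so with a
bias-free head the spatial mean of ``M_c`` equals logit ``c`` exactly.
Maps are kept signed and un-normalized for scoring (normalization would
destroy the logit identity); overlays symmetrically normalize for display
only, red = supports the class, blue = detracts.

On synthetic data with ground-truth trait masks, localization is scored
with the pointing game (CAM argmax inside the mask) and the IoU between
the top-q% CAM pixels and the mask.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from .backbone import ForwardResult
from .genotypes import LABELS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# accuracies


def accuracy_per_image(predictions: pd.DataFrame) -> tuple[float, tuple[float, float]]:
    """Fraction of images with predicted == true, with a Wilson 95% CI.

    ``predictions`` needs columns ``predicted`` and ``true``.
    """
    if len(predictions) == 0:
        raise ValueError("no predictions to score")
    correct = int((predictions["predicted"] == predictions["true"]).sum())
    n = len(predictions)
    lo, hi = proportion_confint(correct, n, alpha=0.05, method="wilson")
    return correct / n, (float(lo), float(hi))


def mode_label(labels: Sequence[str]) -> str:
    """Majority label; exact ties resolve to REFERENCE (documented rule)."""
    votes = sum(1 for l in labels if l == "ALTERNATE")
    return "ALTERNATE" if votes > len(labels) / 2 else "REFERENCE"


def accuracy_per_cultivar(
    predictions: pd.DataFrame,
) -> tuple[float, tuple[float, float]]:
    """Accuracy of the per-cultivar mode of image predictions.

    Needs columns ``cultivar``, ``predicted``, ``true``. Cultivars without
    images are skipped with a warning upstream (they simply do not appear).
    """
    if len(predictions) == 0:
        raise ValueError("no predictions to score")
    correct = 0
    groups = predictions.groupby("cultivar", sort=True)
    for cultivar, g in groups:
        true = g["true"].iloc[0]
        if g["true"].nunique() > 1:
            raise ValueError(f"cultivar {cultivar} has inconsistent true labels")
        if mode_label(list(g["predicted"])) == true:
            correct += 1
    n = groups.ngroups
    lo, hi = proportion_confint(correct, n, alpha=0.05, method="wilson")
    return correct / n, (float(lo), float(hi))


def accuracy_per_plot_day(
    predictions: pd.DataFrame,
) -> tuple[float, tuple[float, float]]:
    """Fraction of plot-day units predicted correctly (same contract as
    per-image accuracy; rows are plot-day units)."""
    return accuracy_per_image(predictions)


# ---------------------------------------------------------------------------
# class activation maps


@dataclass
class CamMap:
    """Signed class-activation heatmap for one image and one class."""

    image_id: str
    class_id: int
    grid: np.ndarray  # (H', W') at feature-map resolution
    upsampled: np.ndarray  # (H, W) at image resolution

    @property
    def spatial_mean(self) -> float:
        return float(self.grid.mean())


def compute_cam(
    forward: ForwardResult,
    class_id: int,
    head_weights: np.ndarray,
    out_size: tuple[int, int] | None = None,
    interpolation: str = "bilinear",
    image_id: str = "",
) -> CamMap:
    """Weighted sum of final-block feature maps by one class's head weights.

    ``M_c(x, y) = sum_k w^c_k f_k(x, y)``; with a bias-free head,
    ``mean_{x,y} M_c = logit_c``. Both the predicted and the non-predicted
    class are valid ``class_id`` values.
    """
    n_classes, d = head_weights.shape
    if not 0 <= class_id < n_classes:
        raise ValueError(f"class_id {class_id} out of range (n={n_classes})")
    maps = forward.feature_maps
    if maps.ndim == 4:
        if maps.shape[0] != 1:
            raise ValueError("compute_cam expects a single image's forward result")
        maps = maps[0]
    if maps.shape[0] != d:
        raise ValueError("head weights and feature maps disagree on d")
    grid = np.tensordot(
        head_weights[class_id].astype(np.float64), maps.astype(np.float64), axes=(0, 0)
    )
    if out_size is None:
        out_size = (grid.shape[0], grid.shape[1])
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    up = resize(grid, out_size, order=order, mode="edge", anti_aliasing=False)
    return CamMap(image_id=image_id, class_id=class_id, grid=grid, upsampled=up)


def rank_activated(
    predictions: pd.DataFrame,
    n: int,
    class_name: str,
    images: Mapping[str, np.ndarray] | None = None,
    luminance_filter: bool = False,
    luminance_range: tuple[float, float] = (0.05, 0.95),
) -> list[str]:
    """Top-n correctly predicted images of a class by that class's logit.

    Deterministic tie-break by image id. The optional luminance filter
    drops badly over-saturated or under-exposed images (mean luminance
    outside ``luminance_range``).
    """
    if class_name not in LABELS:
        raise ValueError(f"unknown class {class_name!r}")
    logit_col = "logit_ref" if class_name == "REFERENCE" else "logit_alt"
    ok = predictions[
        (predictions["predicted"] == class_name)
        & (predictions["predicted"] == predictions["true"])
    ].copy()
    if luminance_filter:
        if images is None:
            raise ValueError("luminance filter requires the images")
        lum = ok["image_id"].map(
            lambda i: float(np.mean(images[i]) / (255.0 if images[i].dtype == np.uint8 else 1.0))
        )
        ok = ok[(lum >= luminance_range[0]) & (lum <= luminance_range[1])]
    ok = ok.sort_values([logit_col, "image_id"], ascending=[False, True])
    if len(ok) < n:
        warnings.warn(f"only {len(ok)} eligible images for top-{n} ranking")
    return list(ok["image_id"].head(n))


def render_overlay(
    image: np.ndarray, cam: CamMap, out: str | Path, alpha: float = 0.5
) -> Path:
    """Alpha-blend a signed CAM onto the image and write a PNG.

    Positive activation tints red, negative tints blue, symmetric about
    zero; an all-zero map leaves the image untinted.
    """
    img = image.astype(np.float64) / (255.0 if image.dtype == np.uint8 else 1.0)
    heat = cam.upsampled
    if heat.shape != img.shape[:2]:
        raise ValueError("CAM must be upsampled to the image size")
    peak = np.abs(heat).max()
    norm = heat / peak if peak > 0 else np.zeros_like(heat)
    tint = np.zeros_like(img)
    tint[..., 0] = np.clip(norm, 0, 1)  # red: supports the class
    tint[..., 2] = np.clip(-norm, 0, 1)  # blue: detracts
    strength = np.abs(norm)[..., None] * alpha
    blended = img * (1 - strength) + tint * strength
    out = Path(out)
    iio.imwrite(out, (np.clip(blended, 0, 1) * 255 + 0.5).astype(np.uint8))
    return out


# ---------------------------------------------------------------------------
# localization scoring against synthetic truth masks


@dataclass
class LocalizationScore:
    image_id: str
    pointing_hit: bool
    iou_topq: float


def _argmax_2d(a: np.ndarray) -> tuple[int, int]:
    idx = int(np.argmax(a))
    return idx // a.shape[1], idx % a.shape[1]


def localization_scores(
    cams: Mapping[str, CamMap],
    masks: Mapping[str, np.ndarray],
    q: float = 10.0,
) -> tuple[list[LocalizationScore], dict]:
    """Pointing-game hits and IoU@top-q% against truth masks.

    Images without a mask (or with an empty mask) are skipped and counted.
    Summary holds the hit rate, mean IoU, and the mask-area fraction (the
    chance level of the pointing game for an uninformative map).
    """
    scores: list[LocalizationScore] = []
    skipped = 0
    area_fracs = []
    for image_id, cam in cams.items():
        mask = masks.get(image_id)
        if mask is None or not mask.any():
            skipped += 1
            continue
        if mask.shape != cam.upsampled.shape:
            raise ValueError(f"mask/CAM shape mismatch for {image_id}")
        r, c = _argmax_2d(cam.upsampled)
        hit = bool(mask[r, c])
        k = max(1, int(round(mask.size * q / 100.0)))
        flat = cam.upsampled.ravel()
        top = np.zeros(mask.size, dtype=bool)
        top[np.argpartition(flat, -k)[-k:]] = True
        top = top.reshape(mask.shape)
        inter = np.logical_and(top, mask).sum()
        union = np.logical_or(top, mask).sum()
        scores.append(
            LocalizationScore(
                image_id=image_id,
                pointing_hit=hit,
                iou_topq=float(inter / union) if union else 0.0,
            )
        )
        area_fracs.append(mask.mean())
    summary = {
        "n_scored": len(scores),
        "n_skipped": skipped,
        "hit_rate": float(np.mean([s.pointing_hit for s in scores])) if scores else np.nan,
        "mean_iou": float(np.mean([s.iou_topq for s in scores])) if scores else np.nan,
        "mask_area_fraction": float(np.mean(area_fracs)) if area_fracs else np.nan,
    }
    return scores, summary


def random_cam_pointing(
    masks: Mapping[str, np.ndarray],
    grid_shape: tuple[int, int],
    n_trials: int,
    seed: int,
) -> float:
    """Monte-Carlo pointing-game baseline: random smooth maps (random
    feature-resolution grids, bilinearly upsampled) pointed at each mask."""
    rng = np.random.default_rng(seed)
    hits = 0
    total = 0
    ids = sorted(k for k, m in masks.items() if m is not None and m.any())
    for _ in range(n_trials):
        for image_id in ids:
            mask = masks[image_id]
            grid = rng.standard_normal(grid_shape)
            up = resize(grid, mask.shape, order=1, mode="edge", anti_aliasing=False)
            r, c = _argmax_2d(up)
            hits += bool(mask[r, c])
            total += 1
    return hits / total if total else np.nan


def pointing_vs_baseline_pvalue(
    hits: int, n: int, baseline_hits: int, baseline_n: int
) -> float:
    """Two-proportion z-test p-value comparing a hit rate with a baseline."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = proportions_ztest(
            np.array([hits, baseline_hits]), np.array([n, baseline_n])
        )
    return float(p)
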