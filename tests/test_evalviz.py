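"""Accuracy units, CAM decomposition, ranking, overlays, localization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import imageio.v3 as iio

from fieldmark.backbone import ForwardResult, ModelSpec, Network, forward
from fieldmark.evalviz import (
    CamMap,
    accuracy_per_cultivar,
    accuracy_per_image,
    accuracy_per_plot_day,
    compute_cam,
    localization_scores,
    mode_label,
    pointing_vs_baseline_pvalue,
    random_cam_pointing,
    rank_activated,
    render_overlay,
)


def _preds(rows):
    return pd.DataFrame(rows, columns=["image_id", "cultivar", "predicted", "true"])


# ---------------------------------------------------------------------------
# accuracies


def test_accuracy_per_image_basic():
    df = _preds(
        [
            ("i1", "c1", "REFERENCE", "REFERENCE"),
            ("i2", "c1", "ALTERNATE", "ALTERNATE"),
            ("i3", "c2", "REFERENCE", "ALTERNATE"),
            ("i4", "c2", "ALTERNATE", "ALTERNATE"),
        ]
    )
    acc, (lo, hi) = accuracy_per_image(df)
    assert acc == 0.75
    assert lo < 0.75 < hi
    assert accuracy_per_image(df[df.predicted == df.true])[0] == 1.0
    with pytest.raises(ValueError):
        accuracy_per_image(df.iloc[0:0])


def test_accuracy_matches_hand_counted_fixture():
    """20-row fixture tallied by hand: 13 correct -> 0.65."""
    rng = np.random.default_rng(0)
    rows = []
    n_correct = 0
    for i in range(20):
        true = "REFERENCE" if i % 2 else "ALTERNATE"
        correct = i % 20 < 13
        pred = true if correct else ("ALTERNATE" if true == "REFERENCE" else "REFERENCE")
        n_correct += correct
        rows.append((f"i{i}", f"c{i % 5}", pred, true))
    assert n_correct == 13
    assert accuracy_per_image(_preds(rows))[0] == pytest.approx(13 / 20)


def test_mode_and_cultivar_accuracy():
    assert mode_label(["REFERENCE", "REFERENCE", "ALTERNATE"]) == "REFERENCE"
    assert mode_label(["REFERENCE", "ALTERNATE"]) == "REFERENCE"  # documented tie
    df = _preds(
        [
            ("i1", "cA", "REFERENCE", "REFERENCE"),
            ("i2", "cA", "REFERENCE", "REFERENCE"),
            ("i3", "cA", "ALTERNATE", "REFERENCE"),
            ("i4", "cB", "REFERENCE", "ALTERNATE"),
            ("i5", "cB", "ALTERNATE", "ALTERNATE"),
        ]
    )
    acc, _ = accuracy_per_cultivar(df)
    # cA mode REFERENCE (correct); cB tie -> REFERENCE (wrong)
    assert acc == 0.5


def test_cultivar_accuracy_agrees_with_bruteforce_majority():
    rng = np.random.default_rng(1)
    rows = []
    for c in range(12):
        true = "REFERENCE" if c % 2 else "ALTERNATE"
        for i in range(int(rng.integers(1, 7))):
            pred = "REFERENCE" if rng.random() < 0.5 else "ALTERNATE"
            rows.append((f"c{c}_i{i}", f"c{c}", pred, true))
    df = _preds(rows)
    acc, _ = accuracy_per_cultivar(df)
    correct = 0
    for c, g in df.groupby("cultivar"):
        n_alt = (g.predicted == "ALTERNATE").sum()
        label = "ALTERNATE" if n_alt > len(g) / 2 else "REFERENCE"
        correct += label == g.true.iloc[0]
    assert acc == pytest.approx(correct / 12)


def test_accuracy_per_plot_day_shares_contract():
    df = _preds([("p1@d0", "c1", "REFERENCE", "REFERENCE"),
                 ("p2@d0", "c2", "ALTERNATE", "REFERENCE")])
    assert accuracy_per_plot_day(df)[0] == 0.5


# ---------------------------------------------------------------------------
# CAM


def _fw(maps, weights):
    maps = np.asarray(maps, dtype=np.float64)
    gap = maps.mean(axis=(1, 2))[None]
    logits = gap @ np.asarray(weights).T
    return ForwardResult(feature_maps=maps[None], gap_vector=gap, logits=logits)


def test_cam_mean_equals_logit_bias_free():
    rng = np.random.default_rng(2)
    maps = rng.standard_normal((5, 4, 4))
    w = rng.standard_normal((2, 5))
    fw = _fw(maps, w)
    for c in range(2):
        cam = compute_cam(fw, c, w)
        assert cam.spatial_mean == pytest.approx(fw.logits[0, c], rel=1e-9)


def test_cam_zero_weights_and_spike():
    maps = np.zeros((3, 4, 4))
    maps[1, 2, 3] = 7.0  # one-hot spatial spike in map 1
    w = np.array([[0.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    fw = _fw(maps, w)
    cam0 = compute_cam(fw, 0, w)
    assert np.all(cam0.grid == 0)
    cam1 = compute_cam(fw, 1, w, out_size=(16, 16))
    r, c = np.unravel_index(np.argmax(cam1.grid), cam1.grid.shape)
    assert (r, c) == (2, 3)


def test_cam_class_bounds_checked():
    fw = _fw(np.zeros((2, 4, 4)), np.zeros((2, 2)))
    with pytest.raises(ValueError):
        compute_cam(fw, 5, np.zeros((2, 2)))


def test_cam_identity_through_real_networks():
    for backbone_id in ("small-4block", "tiny-2block"):
        net = Network(ModelSpec(backbone_id=backbone_id, head_bias=False), seed=0)
        x = np.random.default_rng(3).standard_normal((2, 32, 32, 3)).astype(np.float32)
        result = forward(net, x)
        for i in range(2):
            single = ForwardResult(
                feature_maps=result.feature_maps[i : i + 1],
                gap_vector=result.gap_vector[i : i + 1],
                logits=result.logits[i : i + 1],
            )
            for c in range(2):
                cam = compute_cam(single, c, net.head.weight.value)
                assert cam.spatial_mean == pytest.approx(
                    result.logits[i, c], rel=1e-5, abs=1e-10
                )


# ---------------------------------------------------------------------------
# ranking


def test_rank_activated_sorts_and_filters():
    df = pd.DataFrame(
        {
            "image_id": ["a", "b", "c", "d"],
            "predicted": ["ALTERNATE", "ALTERNATE", "REFERENCE", "ALTERNATE"],
            "true": ["ALTERNATE", "ALTERNATE", "ALTERNATE", "REFERENCE"],
            "logit_ref": [0.0, 0.0, 0.0, 0.0],
            "logit_alt": [2.0, 3.1, 9.0, 5.0],
        }
    )
    # c is misclassified-by-class-filter (predicted REFERENCE), d is wrong
    assert rank_activated(df, 2, "ALTERNATE") == ["b", "a"]
    with pytest.warns(UserWarning, match="eligible"):
        assert rank_activated(df, 5, "ALTERNATE") == ["b", "a"]


def test_rank_activated_matches_sort_oracle():
    rng = np.random.default_rng(4)
    n = 100
    df = pd.DataFrame(
        {
            "image_id": [f"i{k:03d}" for k in range(n)],
            "predicted": rng.choice(["REFERENCE", "ALTERNATE"], n),
            "true": rng.choice(["REFERENCE", "ALTERNATE"], n),
            "logit_ref": rng.standard_normal(n),
            "logit_alt": rng.standard_normal(n),
        }
    )
    got = rank_activated(df, 9, "REFERENCE")
    ok = df[(df.predicted == "REFERENCE") & (df.true == "REFERENCE")]
    expected = list(ok.sort_values(["logit_ref", "image_id"], ascending=[False, True])
                    ["image_id"].head(9))
    assert got == expected


def test_rank_activated_luminance_filter():
    df = pd.DataFrame(
        {
            "image_id": ["dark", "ok"],
            "predicted": ["ALTERNATE"] * 2,
            "true": ["ALTERNATE"] * 2,
            "logit_ref": [0.0, 0.0],
            "logit_alt": [9.0, 1.0],
        }
    )
    images = {
        "dark": np.zeros((8, 8, 3), dtype=np.uint8),
        "ok": np.full((8, 8, 3), 128, dtype=np.uint8),
    }
    with pytest.warns(UserWarning):
        got = rank_activated(df, 2, "ALTERNATE", images=images, luminance_filter=True)
    assert got == ["ok"]


# ---------------------------------------------------------------------------
# overlays


def _cam(arr, image_id="x"):
    arr = np.asarray(arr, dtype=float)
    return CamMap(image_id=image_id, class_id=0, grid=arr, upsampled=arr)


def test_overlay_zero_cam_is_neutral(tmp_path):
    img = np.full((8, 8, 3), 100, dtype=np.uint8)
    out = render_overlay(img, _cam(np.zeros((8, 8))), tmp_path / "o.png")
    written = iio.imread(out)
    assert written.shape == (8, 8, 3)
    assert np.array_equal(written, img)


def test_overlay_sign_flip_swaps_red_blue(tmp_path):
    rng = np.random.default_rng(5)
    gray = (rng.random((8, 8)) * 255).astype(np.uint8)
    img = np.stack([gray] * 3, axis=-1)  # grayscale base isolates the tint
    heat = rng.standard_normal((8, 8))
    a = iio.imread(render_overlay(img, _cam(heat), tmp_path / "a.png"))
    b = iio.imread(render_overlay(img, _cam(-heat), tmp_path / "b.png"))
    assert np.array_equal(a[..., 0], b[..., 2])
    assert np.array_equal(a[..., 2], b[..., 0])
    assert np.array_equal(a[..., 1], b[..., 1])


def test_overlay_requires_upsampled_cam(tmp_path):
    img = np.zeros((8, 8, 3), dtype=np.uint8)
    with pytest.raises(ValueError):
        render_overlay(img, _cam(np.zeros((4, 4))), tmp_path / "x.png")


# ---------------------------------------------------------------------------
# localization


def test_localization_hit_and_identity_iou():
    mask = np.zeros((10, 10), dtype=bool)
    mask[2:4, 2:4] = True  # 4 pixels = 4% of area
    heat = mask.astype(float)  # CAM equals mask -> top-q at q=4% is the mask
    cams = {"a": _cam(heat, "a")}
    scores, summary = localization_scores(cams, {"a": mask}, q=4.0)
    assert scores[0].pointing_hit
    assert scores[0].iou_topq == pytest.approx(1.0)
    assert summary["hit_rate"] == 1.0 and summary["n_skipped"] == 0


def test_localization_skips_missing_masks():
    cams = {"a": _cam(np.ones((4, 4))), "b": _cam(np.ones((4, 4)))}
    scores, summary = localization_scores(cams, {"a": np.ones((4, 4), dtype=bool)})
    assert summary["n_scored"] == 1 and summary["n_skipped"] == 1


def test_random_cam_hit_rate_tracks_mask_area():
    rng = np.random.default_rng(6)
    masks = {}
    for i in range(40):
        m = np.zeros((32, 32), dtype=bool)
        r, c = rng.integers(4, 28, 2)
        m[r - 4 : r + 4, c - 4 : c + 4] = True
        masks[f"m{i}"] = m
    rate = random_cam_pointing(masks, grid_shape=(8, 8), n_trials=25, seed=0)
    area = np.mean([m.mean() for m in masks.values()])
    assert abs(rate - area) < 0.05


def test_two_proportion_pvalue_extremes():
    assert pointing_vs_baseline_pvalue(50, 100, 50, 100) == pytest.approx(1.0)
    assert pointing_vs_baseline_pvalue(95, 100, 10, 100) < 1e-6
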