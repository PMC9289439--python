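"""Synthetic gantry-style field imagery with genotype-controlled traits.

Emulates the statistical structure of overhead plot imagery of a cultivar
panel: each cultivar is grown in a small number of field plots, each plot is
photographed several times per day over a multi-day window, and a genetic
marker family controls a visible trait whose expression can be probabilistic
per image. The renderer is deliberately schematic (textured green canopy
with elliptical leaf strokes), but reproduces the properties the analysis
depends on:

* **Plot identity** — every plot draws persistent appearance latents (tint,
  leaf density/size), so images of one plot resemble each other. This makes
  plot-level metric learning non-trivial and solvable.
* **Genotype-linked traits** — per marker family, carrier cultivars receive
  a trait perturbation (panicle blobs, leaf-midrib contrast, global waxy
  brightening, leaf-edge browning) with amplitude ``effect_size`` and
  per-image expression probability ``expression_prob``. Pixel-exact truth
  masks of the perturbed region are recorded.
* **Class-blind nuisance** — illumination jitter and background texture are
  drawn from random streams independent of genotype, so with
  ``effect_size = 0`` the class-conditional image distributions coincide
  exactly (identical pixels under matched seeds).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import ellipse, ellipse_perimeter, line
from skimage.transform import resize

from .genotypes import (
    FamilyLabel,
    GenotypeTable,
    MarkerFamily,
    SnpCall,
    label_all,
)

_MIN_SIDE = 32  # minimum trait footprint

_LEAF_GREEN = np.array([0.20, 0.42, 0.16])
_PANICLE_COLOR = np.array([0.86, 0.78, 0.45])
_BROWN = np.array([0.45, 0.30, 0.12])


class TraitType(enum.Enum):
    PANICLE_BLOB = "panicle_blob"
    MIDRIB_CONTRAST = "midrib_contrast"
    WAXY_BRIGHTNESS = "waxy_brightness"
    EDGE_BROWNING = "edge_browning"


@dataclass(frozen=True)
class FamilySpec:
    """One marker family and its rendered trait.

    effect_size is the perturbation amplitude beta in [0, 1]; polarity says
    which genotype class carries the visible trait (default ALTERNATE).
    """

    name: str
    trait: TraitType
    effect_size: float = 1.0
    n_snps: int = 1
    polarity: str = "ALTERNATE"
    alt_fraction: float = 0.5
    het_fraction: float = 0.0
    expression_prob: float | None = None  # None: use the campaign default

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if self.expression_prob is not None and not 0.0 < self.expression_prob <= 1.0:
            raise ValueError("expression_prob must lie in (0, 1]")
        if self.polarity not in ("REFERENCE", "ALTERNATE"):
            raise ValueError("polarity must be REFERENCE or ALTERNATE")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0.0 <= self.alt_fraction <= 1.0 or not 0.0 <= self.het_fraction <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class FieldConfig:
    """Synthetic field campaign layout and nuisance levels.

    Defaults mirror the real campaign the generator emulates: a panel of 390
    cultivars, each grown in two spatially separated plots, about 11 usable
    plot images per day over a month-long mid-season window. Tests and the
    worked examples use much smaller layouts passed explicitly.
    """

    n_cultivars: int = 390
    plots_per_cultivar: int = 2
    n_days: int = 30
    images_per_plot_day: int = 11
    image_size: tuple[int, int] = (512, 512)
    families: tuple[FamilySpec, ...] = (
        FamilySpec(name="fam_panicle", trait=TraitType.PANICLE_BLOB),
    )
    expression_prob: float = 1.0
    illumination_sigma: float = 0.05
    texture_scale: float = 0.08
    plot_signature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (
            ("n_cultivars", self.n_cultivars),
            ("plots_per_cultivar", self.plots_per_cultivar),
            ("n_days", self.n_days),
            ("images_per_plot_day", self.images_per_plot_day),
        ):
            if v < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.expression_prob <= 1.0:
            raise ValueError("expression_prob must lie in (0, 1]")
        if min(self.image_size) < _MIN_SIDE:
            raise ValueError(
                f"image_size {self.image_size} smaller than the minimum "
                f"trait footprint ({_MIN_SIDE} px)"
            )
        if len(self.families) == 0:
            raise ValueError("at least one marker family is required")

    @property
    def n_images(self) -> int:
        return (
            self.n_cultivars
            * self.plots_per_cultivar
            * self.n_days
            * self.images_per_plot_day
        )


def simulate_genotypes(config: FieldConfig) -> tuple[GenotypeTable, dict[str, MarkerFamily]]:
    """Draw a cultivar x SNP call table consistent with the family specs.

    Per family: ``alt_fraction`` of cultivars are made carriers of at least
    one homozygous-alternate member SNP, ``het_fraction`` get a single
    heterozygous call (and are later EXCLUDED by the labeling rule), and the
    rest are homozygous-reference throughout. Seeded and deterministic.
    """
    cultivars = [f"c{i:04d}" for i in range(config.n_cultivars)]
    columns: dict[str, np.ndarray] = {}
    families: dict[str, MarkerFamily] = {}
    for fi, fam in enumerate(config.families):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0, fi)))
        n = config.n_cultivars
        n_alt = int(round(n * fam.alt_fraction))
        n_het = min(int(round(n * fam.het_fraction)), n - n_alt)
        roles = np.array(["REF"] * n, dtype=object)
        order = rng.permutation(n)
        roles[order[:n_alt]] = "ALT"
        roles[order[n_alt : n_alt + n_het]] = "HET"
        snp_ids = tuple(f"{fam.name}_snp{j}" for j in range(fam.n_snps))
        families[fam.name] = MarkerFamily(name=fam.name, snp_ids=snp_ids)
        calls = np.full((n, fam.n_snps), int(SnpCall.HOM_REF), dtype=np.int8)
        for i in range(n):
            if roles[i] == "ALT":
                k = int(rng.integers(1, fam.n_snps + 1))
                which = rng.choice(fam.n_snps, size=k, replace=False)
                calls[i, which] = int(SnpCall.HOM_ALT)
            elif roles[i] == "HET":
                calls[i, int(rng.integers(fam.n_snps))] = int(SnpCall.HET)
        for j, sid in enumerate(snp_ids):
            columns[sid] = calls[:, j]
    table = GenotypeTable(
        calls=pd.DataFrame(columns, index=pd.Index(cultivars, name="cultivar"))
    )
    return table, families


# ---------------------------------------------------------------------------
# rendering


@dataclass
class _PlotLatent:
    tint: np.ndarray
    n_leaves: int
    leaf_scale: float


def _plot_latent(config: FieldConfig, plot_index: int) -> _PlotLatent:
    # Plots of one crop species look nearly alike; their appearance
    # signature is subtle (slight stand-density and hue differences), so
    # plot identification cannot be solved from a color histogram alone.
    # ``plot_signature`` scales the signature strength (0 = no persistent
    # plot appearance at all).
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1, plot_index)))
    s = config.plot_signature
    return _PlotLatent(
        tint=rng.normal(0.0, 0.012, size=3) * s,
        n_leaves=int(round(20 + s * (int(rng.integers(16, 24)) - 20))),
        leaf_scale=float(1.0 + s * (rng.uniform(0.9, 1.12) - 1.0)),
    )


def _draw_background(
    config: FieldConfig, latent: _PlotLatent, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple]]:
    """Textured canopy: low-frequency value noise plus elliptical leaf
    strokes. Returns the float image and the leaf geometry list
    (cy, cx, a, b, angle) used by the trait operators."""
    h, w = config.image_size
    img = np.empty((h, w, 3))
    img[:] = _LEAF_GREEN * 1.05 + latent.tint
    coarse = rng.normal(0.0, config.texture_scale, size=(6, 6))
    noise = resize(coarse, (h, w), order=1, mode="reflect", anti_aliasing=False)
    img += noise[:, :, None]
    leaves = []
    for _ in range(latent.n_leaves):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a = rng.uniform(h / 8, h / 4) * latent.leaf_scale
        b = a * rng.uniform(0.18, 0.32)
        angle = rng.uniform(0, np.pi)
        shade = 1.0 + rng.normal(0.0, 0.18)
        rr, cc = ellipse(cy, cx, a, b, shape=(h, w), rotation=angle)
        img[rr, cc] = 0.6 * img[rr, cc] + 0.4 * (_LEAF_GREEN * shade + latent.tint)
        leaves.append((cy, cx, a, b, angle))
    return img, leaves


def _apply_trait(
    img: np.ndarray,
    trait: TraitType,
    beta: float,
    leaves: list[tuple],
    rng: np.random.Generator,
) -> np.ndarray:
    """Perturb ``img`` in place with amplitude ``beta``; return the boolean
    mask of perturbed pixels. The mask is computed even at ``beta = 0`` (it
    marks where the trait *would* render), so localization baselines remain
    scorable on zero-effect data; at ``beta = 0`` the pixels are untouched.
    """
    h, w = img.shape[:2]
    mask = np.zeros((h, w), dtype=bool)
    if trait is TraitType.PANICLE_BLOB:
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(int(rng.integers(2, 5))):
            r = rng.uniform(h / 8, h / 6)  # panicles are large canopy features
            cy = rng.uniform(r, h - r)
            cx = rng.uniform(r, w - r)
            dist = np.hypot(yy - cy, xx - cx)
            falloff = np.clip(1.0 - dist / r, 0.0, 1.0)
            # grain speckle: panicles are textured seed clusters, not
            # smooth discs — gives them a high-frequency signature
            speckle = rng.uniform(0.55, 1.0, size=(h, w))
            amp = falloff * speckle
            img += beta * amp[:, :, None] * (_PANICLE_COLOR - img)
            mask |= falloff > 0.0  # full perturbed footprint
    elif trait is TraitType.MIDRIB_CONTRAST:
        k = min(len(leaves), 6)
        idx = rng.choice(len(leaves), size=k, replace=False)
        for i in idx:
            cy, cx, a, b, angle = leaves[i]
            dy, dx = 0.8 * a * np.sin(angle), 0.8 * a * np.cos(angle)
            r0, c0 = int(round(cy - dy)), int(round(cx - dx))
            r1, c1 = int(round(cy + dy)), int(round(cx + dx))
            for off in (0, 1):
                rr, cc = line(r0 + off, c0, r1 + off, c1)
                keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                rr, cc = rr[keep], cc[keep]
                img[rr, cc] += beta * 0.6 * (1.0 - img[rr, cc])
                mask[rr, cc] = True
    elif trait is TraitType.WAXY_BRIGHTNESS:
        img += beta * 0.22 * (1.0 - img)
        mask[:] = True
    elif trait is TraitType.EDGE_BROWNING:
        k = min(len(leaves), 6)
        idx = rng.choice(len(leaves), size=k, replace=False)
        for i in idx:
            cy, cx, a, b, angle = leaves[i]
            rr, cc = ellipse_perimeter(
                int(round(cy)), int(round(cx)), int(round(a)), int(round(b)),
                orientation=angle, shape=(h, w),
            )
            img[rr, cc] += beta * 0.8 * (_BROWN - img[rr, cc])
            mask[rr, cc] = True
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"no rendering operator for {trait}")
    return mask


def render_image(
    config: FieldConfig,
    plot_index: int,
    day: int,
    image_index: int,
    expressed_traits: Iterable[tuple[TraitType, float]] = (),
) -> tuple[np.ndarray, np.ndarray | None]:
    """Render one plot image; returns (uint8 RGB image, mask or None).

    ``expressed_traits`` lists (trait, effect_size) pairs that this image
    expresses. Background, trait, and nuisance randomness come from three
    independent seeded streams keyed by (seed, plot, day, image index), so
    class membership never leaks through the nuisance draws: two images that
    differ only in trait expression share identical background and
    illumination.
    """
    latent = _plot_latent(config, plot_index)
    key = (config.seed, 2, plot_index, day, image_index)
    rng_bg = np.random.default_rng(np.random.SeedSequence(key + (0,)))
    rng_trait = np.random.default_rng(np.random.SeedSequence(key + (1,)))
    rng_nuis = np.random.default_rng(np.random.SeedSequence(key + (2,)))
    img, leaves = _draw_background(config, latent, rng_bg)
    mask = None
    for trait, beta in expressed_traits:
        m = _apply_trait(img, trait, beta, leaves, rng_trait)
        mask = m if mask is None else (mask | m)
    gain = 1.0 + rng_nuis.normal(0.0, config.illumination_sigma)
    img = np.clip(img * gain, 0.0, 1.0)
    return (img * 255.0 + 0.5).astype(np.uint8), mask


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class SyntheticDataset:
    """In-memory synthetic campaign: images, truth masks, genotypes, layout."""

    config: FieldConfig
    genotypes: GenotypeTable
    families: dict[str, MarkerFamily]
    plot_map: pd.DataFrame  # columns: plot, cultivar
    manifest: pd.DataFrame  # image_id, cultivar, plot, day, image_index, expresses_<fam>
    images: dict[str, np.ndarray]
    masks: dict[str, dict[str, np.ndarray]]  # family -> image_id -> bool mask

    def labels(self, family: str | None = None) -> dict[str, FamilyLabel]:
        family = family or next(iter(self.families))
        return label_all(self.genotypes, self.families[family])

    def images_by_cultivar(self) -> dict[str, list[str]]:
        return {
            c: list(g["image_id"])
            for c, g in self.manifest.groupby("cultivar", sort=True)
        }

    def image_meta(self) -> pd.DataFrame:
        return self.manifest.set_index("image_id")

    def masks_for(self, family: str | None = None) -> dict[str, np.ndarray]:
        family = family or next(iter(self.families))
        return self.masks[family]


def generate_arrays(config: FieldConfig) -> SyntheticDataset:
    """Generate the full campaign in memory (images, masks, tables)."""
    genotypes, families = simulate_genotypes(config)
    cultivars = genotypes.cultivars
    fam_labels = {
        name: label_all(genotypes, fam) for name, fam in families.items()
    }
    carriers = {
        spec.name: {
            c
            for c in cultivars
            if fam_labels[spec.name][c].value == spec.polarity
        }
        for spec in config.families
    }
    plot_rows = []
    manifest_rows = []
    images: dict[str, np.ndarray] = {}
    masks: dict[str, dict[str, np.ndarray]] = {spec.name: {} for spec in config.families}
    plot_index = 0
    for ci, cultivar in enumerate(cultivars):
        for p in range(config.plots_per_cultivar):
            plot_id = f"p{plot_index:04d}"
            plot_rows.append((plot_id, cultivar))
            for day in range(config.n_days):
                for k in range(config.images_per_plot_day):
                    image_id = f"{plot_id}_d{day:02d}_i{k:02d}"
                    expressed: list[tuple[TraitType, float]] = []
                    row: dict = {
                        "image_id": image_id,
                        "cultivar": cultivar,
                        "plot": plot_id,
                        "day": day,
                        "image_index": k,
                    }
                    for fi, spec in enumerate(config.families):
                        rng_expr = np.random.default_rng(
                            np.random.SeedSequence(
                                (config.seed, 3, fi, plot_index, day, k)
                            )
                        )
                        pi = (
                            spec.expression_prob
                            if spec.expression_prob is not None
                            else config.expression_prob
                        )
                        expresses = bool(
                            cultivar in carriers[spec.name]
                            and rng_expr.random() < pi
                        )
                        row[f"expresses_{spec.name}"] = expresses
                        if expresses:
                            expressed.append((spec.trait, spec.effect_size))
                    img, mask = render_image(
                        config, plot_index, day, k, expressed
                    )
                    images[image_id] = img
                    # single mask per image is attributed to every family it
                    # expresses (one family active is the default setup)
                    if mask is not None:
                        for fi, spec in enumerate(config.families):
                            if row[f"expresses_{spec.name}"]:
                                masks[spec.name][image_id] = mask
                    manifest_rows.append(row)
            plot_index += 1
    manifest = pd.DataFrame(manifest_rows)
    plot_map = pd.DataFrame(plot_rows, columns=["plot", "cultivar"])
    return SyntheticDataset(
        config=config,
        genotypes=genotypes,
        families=families,
        plot_map=plot_map,
        manifest=manifest,
        images=images,
        masks=masks,
    )


def generate_dataset(config: FieldConfig, out_dir: str | Path) -> pd.DataFrame:
    """Generate the campaign and write it to disk.

    Layout: ``images/<id>.png``, ``masks/<family>/<id>.png`` (expressing
    images only), ``genotypes.tsv``, ``plot_map.csv``, ``manifest.csv``.
    Returns the manifest. Image count equals
    n_cultivars x plots_per_cultivar x n_days x images_per_plot_day.
    """
    out = Path(out_dir)
    try:
        (out / "images").mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    ds = generate_arrays(config)
    for image_id, img in ds.images.items():
        iio.imwrite(out / "images" / f"{image_id}.png", img)
    mask_paths: dict[str, str] = {}
    for fam_name, fam_masks in ds.masks.items():
        fam_dir = out / "masks" / fam_name
        fam_dir.mkdir(parents=True, exist_ok=True)
        for image_id, mask in fam_masks.items():
            path = fam_dir / f"{image_id}.png"
            iio.imwrite(path, (mask.astype(np.uint8) * 255))
            mask_paths[image_id] = str(path.relative_to(out))
    ds.genotypes.to_tsv(out / "genotypes.tsv")
    ds.plot_map.to_csv(out / "plot_map.csv", index=False)
    manifest = ds.manifest.copy()
    manifest["mask_path"] = manifest["image_id"].map(mask_paths).fillna("")
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_images(directory: str | Path, image_ids: Iterable[str]) -> dict[str, np.ndarray]:
    """Load PNG images written by :func:`generate_dataset`."""
    directory = Path(directory)
    return {iid: iio.imread(directory / "images" / f"{iid}.png") for iid in image_ids}
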