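"""Genotype tables, marker-family labeling, balanced splits and batch plans.

A *marker family* is a named group of related SNPs treated as a single unit.
Cultivars are labeled per family: a cultivar is ALTERNATE when it is
homozygous-alternate for at least one member SNP, REFERENCE when it is
homozygous-reference for every member SNP, and EXCLUDED otherwise (any
heterozygous or missing call with no homozygous-alternate call elsewhere in
the family). Heterozygous cultivars are not modeled.

Splits keep train and test cultivars disjoint and balance the test set so a
label-blind predictor scores 50% both per image and per cultivar.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed class order used everywhere: index 0 = REFERENCE, index 1 = ALTERNATE.
LABELS = ("REFERENCE", "ALTERNATE")


class SnpCall(enum.IntEnum):
    """Diploid biallelic genotype call at one SNP."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = 3

    @classmethod
    def from_string(cls, text: str) -> "SnpCall":
        """Parse a VCF-style GT string (``0/0``, ``0/1``, ``1/1``, ``./.``).

        Phased separators (``|``) are accepted. Anything unparseable maps to
        MISSING (callers count these and warn).
        """
        alleles = text.strip().replace("|", "/").split("/")
        if len(alleles) != 2:
            return cls.MISSING
        a, b = alleles
        if a == "0" and b == "0":
            return cls.HOM_REF
        if a == "1" and b == "1":
            return cls.HOM_ALT
        if {a, b} == {"0", "1"}:
            return cls.HET
        return cls.MISSING


class FamilyLabel(enum.Enum):
    REFERENCE = "REFERENCE"
    ALTERNATE = "ALTERNATE"
    EXCLUDED = "EXCLUDED"


@dataclass
class GenotypeTable:
    """Cultivar x SNP table of :class:`SnpCall` values.

    Parameters
    ----------
    calls : pandas.DataFrame
        Integer codes (``SnpCall`` values), index = cultivar ids,
        columns = SNP ids. Every cell must hold one of the four states.
    snp_meta : pandas.DataFrame, optional
        Opaque per-SNP metadata (chromosome, gene, position), indexed by
        SNP id.
    """

    calls: pd.DataFrame
    snp_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            raise ValueError("duplicate cultivar ids in genotype table")
        if self.calls.columns.has_duplicates:
            raise ValueError("duplicate SNP ids in genotype table")
        valid = {int(c) for c in SnpCall}
        observed = set(np.unique(self.calls.to_numpy()))
        if not observed <= valid:
            raise ValueError(f"invalid call codes present: {observed - valid}")

    @property
    def cultivars(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snps(self) -> list[str]:
        return list(self.calls.columns)

    def call(self, cultivar: str, snp: str) -> SnpCall:
        return SnpCall(int(self.calls.at[cultivar, snp]))

    def to_tsv(self, path: str | Path) -> None:
        """Write the table in the plain TSV interchange format."""
        text_map = {
            SnpCall.HOM_REF: "0/0",
            SnpCall.HET: "0/1",
            SnpCall.HOM_ALT: "1/1",
            SnpCall.MISSING: "./.",
        }
        out = self.calls.map(lambda c: text_map[SnpCall(int(c))])
        out.index.name = "cultivar"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class MarkerFamily:
    """Named group of related SNPs treated as one labeling unit."""

    name: str
    snp_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.snp_ids) == 0:
            raise ValueError(f"marker family {self.name!r} has no SNPs")

    def validate_against(self, table: GenotypeTable) -> None:
        missing = set(self.snp_ids) - set(table.snps)
        if missing:
            raise ValueError(
                f"family {self.name!r} references SNPs absent from the "
                f"genotype table: {sorted(missing)}"
            )


def load_genotypes(path: str | Path, format: str = "tsv") -> GenotypeTable:
    """Load a genotype table from TSV or a minimal VCF.

    TSV layout: header ``cultivar<TAB>snp1<TAB>...``, one row per cultivar,
    calls encoded ``0/0 | 0/1 | 1/1 | ./.``. VCF: GT field only, samples are
    cultivars. Unparseable calls become MISSING with a logged warning count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _load_tsv(path)
    if format in ("vcf", "vcf-like"):
        return _load_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _load_tsv(path: Path) -> GenotypeTable:
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.columns[0].lower() != "cultivar":
        raise ValueError(
            f"malformed genotype TSV header: first column is "
            f"{raw.columns[0]!r}, expected 'cultivar'"
        )
    if raw.iloc[:, 0].duplicated().any():
        dups = raw.iloc[:, 0][raw.iloc[:, 0].duplicated()].tolist()
        raise ValueError(f"duplicate cultivar ids: {dups}")
    raw = raw.set_index(raw.columns[0])
    n_bad = 0
    parseable = {"0/0", "0/1", "1/0", "1/1", "./.", "0|0", "0|1", "1|0", "1|1", ".|."}
    codes = np.empty(raw.shape, dtype=np.int8)
    for j, col in enumerate(raw.columns):
        for i, text in enumerate(raw[col].astype(str)):
            call = SnpCall.from_string(text)
            if call is SnpCall.MISSING and text.strip() not in parseable:
                n_bad += 1
            codes[i, j] = int(call)
    if n_bad:
        logger.warning("%d unparseable genotype calls mapped to MISSING", n_bad)
    calls = pd.DataFrame(codes, index=raw.index.rename("cultivar"), columns=raw.columns)
    return GenotypeTable(calls=calls)


def _load_vcf(path: Path) -> GenotypeTable:
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    cultivars = list(vcf.samples)
    if len(set(cultivars)) != len(cultivars):
        raise ValueError("duplicate cultivar (sample) ids in VCF")
    gt_map = {0: SnpCall.HOM_REF, 1: SnpCall.HET, 2: SnpCall.MISSING, 3: SnpCall.HOM_ALT}
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    meta: list[dict] = []
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        snp_ids.append(vid)
        meta.append({"snp": vid, "chromosome": variant.CHROM, "position": variant.POS})
        rows.append(np.array([int(gt_map[int(t)]) for t in variant.gt_types], dtype=np.int8))
    if len(set(snp_ids)) != len(snp_ids):
        raise ValueError("duplicate SNP ids in VCF")
    codes = np.stack(rows, axis=1) if rows else np.empty((len(cultivars), 0), np.int8)
    calls = pd.DataFrame(codes, index=pd.Index(cultivars, name="cultivar"), columns=snp_ids)
    snp_meta = pd.DataFrame(meta).set_index("snp") if meta else None
    return GenotypeTable(calls=calls, snp_meta=snp_meta)


def label_cultivar(
    table: GenotypeTable, family: MarkerFamily, cultivar: str
) -> FamilyLabel:
    """Label one cultivar reference/alternate for a marker family.

    ALTERNATE if at least one family SNP is homozygous-alternate (one
    polymorphism can already alter the phenotype); REFERENCE only if every
    family SNP is homozygous-reference; EXCLUDED otherwise (heterozygous or
    missing calls present without any homozygous-alternate).
    """
    family.validate_against(table)
    if cultivar not in table.calls.index:
        raise KeyError(f"cultivar {cultivar!r} not in genotype table")
    calls = [table.call(cultivar, s) for s in family.snp_ids]
    if any(c is SnpCall.HOM_ALT for c in calls):
        return FamilyLabel.ALTERNATE
    if all(c is SnpCall.HOM_REF for c in calls):
        return FamilyLabel.REFERENCE
    return FamilyLabel.EXCLUDED


def label_all(table: GenotypeTable, family: MarkerFamily) -> dict[str, FamilyLabel]:
    """Label every cultivar in the table for one family."""
    return {c: label_cultivar(table, family, c) for c in table.cultivars}


@dataclass
class DatasetSplit:
    """Disjoint-cultivar train/test split with a class-balanced test set.

    ``train`` and ``test`` are DataFrames with columns
    ``image_id, cultivar, label`` (label is ``"REFERENCE"``/``"ALTERNATE"``).
    """

    train: pd.DataFrame
    test: pd.DataFrame
    seed: int

    @property
    def train_cultivars(self) -> set[str]:
        return set(self.train["cultivar"])

    @property
    def test_cultivars(self) -> set[str]:
        return set(self.test["cultivar"])

    def validate(self) -> None:
        if self.train_cultivars & self.test_cultivars:
            raise AssertionError("train/test cultivars overlap")
        counts = self.test["label"].value_counts()
        if counts.get("REFERENCE", 0) != counts.get("ALTERNATE", 0):
            raise AssertionError("test image classes are not balanced")
        cc = self.test.groupby("label")["cultivar"].nunique()
        if cc.get("REFERENCE", 0) != cc.get("ALTERNATE", 0):
            raise AssertionError("test cultivar classes are not balanced")

    def to_manifest(
        self, path: str | Path, image_meta: pd.DataFrame | None = None
    ) -> pd.DataFrame:
        """Write the split manifest CSV (image_id, cultivar, plot, day,
        label, partition, seed). Plot/day come from ``image_meta`` when given
        (indexed by image_id)."""
        parts = []
        for name, df in (("train", self.train), ("test", self.test)):
            d = df.copy()
            d["partition"] = name
            parts.append(d)
        manifest = pd.concat(parts, ignore_index=True)
        if image_meta is not None:
            extra = image_meta.reindex(manifest["image_id"])
            for col in ("plot", "day"):
                if col in extra.columns:
                    manifest[col] = extra[col].to_numpy()
        manifest["seed"] = self.seed
        cols = [c for c in ("image_id", "cultivar", "plot", "day", "label", "partition", "seed")
                if c in manifest.columns]
        manifest = manifest[cols]
        manifest.to_csv(path, index=False)
        return manifest

    @classmethod
    def from_manifest(cls, path: str | Path) -> "DatasetSplit":
        manifest = pd.read_csv(path)
        seed = int(manifest["seed"].iloc[0])
        cols = ["image_id", "cultivar", "label"]
        train = manifest.loc[manifest["partition"] == "train", cols].reset_index(drop=True)
        test = manifest.loc[manifest["partition"] == "test", cols].reset_index(drop=True)
        return cls(train=train, test=test, seed=seed)


def make_split(
    labels: Mapping[str, FamilyLabel],
    images: Mapping[str, Sequence[str]],
    seed: int,
) -> DatasetSplit:
    """Build a disjoint-cultivar split with a balanced test set.

    The test set takes ``floor(min_class_count / 2)`` cultivars from each
    class (sampled with ``seed``); their images are then subsampled so both
    classes contribute the same number of test images (the minimum of the
    two class totals), keeping at least one image per test cultivar so the
    cultivar balance survives the image balance. All remaining labeled
    cultivars, with all their images, form the training set. EXCLUDED
    cultivars are dropped first. Deterministic for a given seed and
    invariant to input ordering.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {"REFERENCE": [], "ALTERNATE": []}
    for cultivar in sorted(labels):
        lab = labels[cultivar]
        if lab is FamilyLabel.EXCLUDED:
            continue
        by_class[lab.value].append(cultivar)
    for cls_name, cultivars in by_class.items():
        if len(cultivars) < 2:
            raise ValueError(
                f"unsplittable marker: class {cls_name} has "
                f"{len(cultivars)} labeled cultivars (need >= 2)"
            )
    n_test = min(len(v) for v in by_class.values()) // 2
    # seeded preference order per class; a shrinking test size (degenerate,
    # image-poor inputs) keeps a prefix of this order
    order = {
        cls_name: list(rng.permutation(np.array(by_class[cls_name])))
        for cls_name in LABELS
    }
    imgs_of = {
        c: sorted(images.get(c, [])) for cultivars in by_class.values() for c in cultivars
    }
    while n_test >= 1:
        chosen = {cls_name: order[cls_name][:n_test] for cls_name in LABELS}
        n_imgs = min(
            sum(len(imgs_of[c]) for c in chosen[cls_name]) for cls_name in LABELS
        )
        if n_imgs >= n_test:
            break
        n_test = n_imgs
    else:
        raise ValueError("unsplittable marker: a test class has no images")
    test_rows, train_rows = [], []
    for cls_name in LABELS:
        picked = set(chosen[cls_name])
        for cultivar in by_class[cls_name]:
            if cultivar not in picked:
                train_rows.extend(
                    (img, cultivar, cls_name) for img in imgs_of[cultivar]
                )
        # image subsample protecting one image per chosen cultivar
        protected, rest = [], []
        for cultivar in chosen[cls_name]:
            imgs = imgs_of[cultivar]
            keep = int(rng.integers(len(imgs)))
            protected.append((imgs[keep], cultivar))
            rest.extend((img, cultivar) for i, img in enumerate(imgs) if i != keep)
        n_extra = n_imgs - len(protected)
        if n_extra < len(rest):
            idx = rng.choice(len(rest), size=n_extra, replace=False)
            rest = [rest[i] for i in sorted(idx)]
        test_rows.extend(
            (img, cultivar, cls_name) for img, cultivar in protected + rest
        )
    split = DatasetSplit(
        train=pd.DataFrame(train_rows, columns=["image_id", "cultivar", "label"]),
        test=pd.DataFrame(test_rows, columns=["image_id", "cultivar", "label"]),
        seed=seed,
    )
    split.validate()
    return split


@dataclass
class BatchPlan:
    """Epoch-long list of class-balanced batches of image ids."""

    batches: list[list[str]]
    batch_size: int


def plan_balanced_batches(
    train: pd.DataFrame, batch_size: int, seed: int
) -> BatchPlan:
    """Plan one epoch of batches with per-batch class balance.

    Each full batch holds ``ceil(b/2)`` images of one class and
    ``floor(b/2)`` of the other (which class gets the extra slot alternates
    for odd ``b``). Every majority-class image is scheduled about once per
    epoch; the minority class is re-sampled with replacement once its
    shuffled queue is exhausted. Fully seeded.
    """
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    rng = np.random.default_rng(seed)
    queues: dict[str, list[str]] = {}
    pools: dict[str, np.ndarray] = {}
    for cls_name in LABELS:
        ids = np.sort(train.loc[train["label"] == cls_name, "image_id"].to_numpy())
        if len(ids) == 0:
            raise ValueError(f"training set has no {cls_name} images")
        pools[cls_name] = ids
        queues[cls_name] = list(rng.permutation(ids))
    n_total = sum(len(p) for p in pools.values())
    n_batches = max(1, int(np.ceil(n_total / batch_size)))
    half_hi = int(np.ceil(batch_size / 2))
    half_lo = batch_size // 2

    def draw(cls_name: str, n: int) -> list[str]:
        out: list[str] = []
        q = queues[cls_name]
        while len(out) < n:
            if not q:
                q.extend(rng.choice(pools[cls_name], size=len(pools[cls_name]), replace=True))
            out.append(q.pop())
        return out

    batches = []
    for b in range(n_batches):
        if batch_size % 2 == 0:
            counts = (half_lo, half_lo)
        else:
            counts = (half_hi, half_lo) if b % 2 == 0 else (half_lo, half_hi)
        batch = draw("REFERENCE", counts[0]) + draw("ALTERNATE", counts[1])
        order = rng.permutation(len(batch))
        batches.append([batch[i] for i in order])
    return BatchPlan(batches=batches, batch_size=batch_size)


def load_marker_families(path: str | Path) -> dict[str, MarkerFamily]:
    """Read a marker-family file: ``family<TAB>snp_id`` rows (one per SNP).

    Extra columns (chromosome, gene, position, phenotype notes) are
    carried as opaque metadata and ignored here.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["family", "snp"]:
        raise ValueError("marker-family file must have columns 'family', 'snp'")
    return {
        name: MarkerFamily(name=name, snp_ids=tuple(group["snp"]))
        for name, group in df.groupby("family", sort=True)
    }


def bundled_marker_families() -> dict[str, MarkerFamily]:
    """The five sorghum bioenergy-panel marker families shipped with the
    package (leaf wax, dw, d locus, ma, tan), for use as realistic family
    definitions against user genotype tables."""
    path = Path(__file__).parent / "data" / "bap_marker_families.tsv"
    return load_marker_families(path)
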