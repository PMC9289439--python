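"""Genotype ingestion, family labeling, splits, and batch planning."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fieldmark.genotypes import (
    BatchPlan,
    DatasetSplit,
    FamilyLabel,
    GenotypeTable,
    MarkerFamily,
    SnpCall,
    label_all,
    label_cultivar,
    load_genotypes,
    load_marker_families,
    make_split,
    plan_balanced_batches,
)


def table_from_calls(calls: dict[str, list[SnpCall]], snps: list[str]) -> GenotypeTable:
    data = {s: [int(calls[c][j]) for c in calls] for j, s in enumerate(snps)}
    return GenotypeTable(
        calls=pd.DataFrame(data, index=pd.Index(list(calls), name="cultivar"), dtype=np.int8)
    )


# ---------------------------------------------------------------------------
# parsing


@pytest.mark.parametrize(
    "text,expected",
    [
        ("0/0", SnpCall.HOM_REF),
        ("1/1", SnpCall.HOM_ALT),
        ("0/1", SnpCall.HET),  # one normal and one variant copy
        ("1/0", SnpCall.HET),
        ("0|1", SnpCall.HET),
        ("./.", SnpCall.MISSING),
        ("garbage", SnpCall.MISSING),
    ],
)
def test_gt_string_parsing(text, expected):
    assert SnpCall.from_string(text) is expected


def test_load_tsv_roundtrip(tmp_path):
    path = tmp_path / "geno.tsv"
    path.write_text("cultivar\tsnpA\tsnpB\ncultA\t0/0\t0/0\ncultB\t1/1\t./.\n")
    table = load_genotypes(path)
    assert table.cultivars == ["cultA", "cultB"]
    assert table.snps == ["snpA", "snpB"]
    assert table.call("cultA", "snpA") is SnpCall.HOM_REF
    assert table.call("cultA", "snpB") is SnpCall.HOM_REF
    assert table.call("cultB", "snpB") is SnpCall.MISSING
    # write/read cycle preserves every call
    out = tmp_path / "copy.tsv"
    table.to_tsv(out)
    again = load_genotypes(out)
    assert again.calls.equals(table.calls)


def test_load_tsv_rejects_bad_header_and_duplicates(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("notcultivar\tsnpA\nx\t0/0\n")
    with pytest.raises(ValueError, match="header"):
        load_genotypes(bad)
    dup = tmp_path / "dup.tsv"
    dup.write_text("cultivar\tsnpA\na\t0/0\na\t1/1\n")
    with pytest.raises(ValueError, match="duplicate"):
        load_genotypes(dup)


def test_load_minimal_vcf(tmp_path):
    vcf = tmp_path / "geno.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tcultA\tcultB\n"
        "6\t42805319\tsnp1\tG\tA\t.\t.\t.\tGT\t0/0\t1/1\n"
        "6\t42804037\tsnp2\tC\tT\t.\t.\t.\tGT\t0/1\t./.\n"
    )
    table = load_genotypes(vcf, format="vcf")
    assert table.cultivars == ["cultA", "cultB"]
    assert table.call("cultA", "snp1") is SnpCall.HOM_REF
    assert table.call("cultB", "snp1") is SnpCall.HOM_ALT
    assert table.call("cultA", "snp2") is SnpCall.HET
    assert table.call("cultB", "snp2") is SnpCall.MISSING


def test_marker_family_file(tmp_path):
    path = tmp_path / "families.tsv"
    path.write_text("family\tsnp\nleaf_wax\ts1\nleaf_wax\ts2\ndw\ts3\n")
    fams = load_marker_families(path)
    assert fams["leaf_wax"].snp_ids == ("s1", "s2")
    assert fams["dw"].snp_ids == ("s3",)


def test_bundled_marker_families_ship_with_package():
    from fieldmark.genotypes import bundled_marker_families

    fams = bundled_marker_families()
    assert set(fams) == {"leaf_wax", "dw", "d_locus", "ma", "tan"}
    assert len(fams["d_locus"].snp_ids) == 6
    assert len(fams["leaf_wax"].snp_ids) == 4
    assert len(fams["tan"].snp_ids) == 1


# ---------------------------------------------------------------------------
# labeling rule


@pytest.mark.parametrize(
    "calls,expected",
    [
        ([SnpCall.HOM_REF] * 3, FamilyLabel.REFERENCE),
        ([SnpCall.HOM_REF, SnpCall.HOM_ALT], FamilyLabel.ALTERNATE),
        ([SnpCall.HET, SnpCall.HOM_REF], FamilyLabel.EXCLUDED),
        ([SnpCall.MISSING], FamilyLabel.EXCLUDED),
        ([SnpCall.HET, SnpCall.HOM_ALT], FamilyLabel.ALTERNATE),
    ],
)
def test_label_rule_examples(calls, expected):
    snps = [f"s{i}" for i in range(len(calls))]
    table = table_from_calls({"c": calls}, snps)
    fam = MarkerFamily(name="f", snp_ids=tuple(snps))
    assert label_cultivar(table, fam, "c") is expected


def truth_table_label(calls: tuple[SnpCall, ...]) -> FamilyLabel:
    """Independent oracle: literal restatement of the labeling rule."""
    if SnpCall.HOM_ALT in calls:
        return FamilyLabel.ALTERNATE
    if all(c is SnpCall.HOM_REF for c in calls):
        return FamilyLabel.REFERENCE
    return FamilyLabel.EXCLUDED


@pytest.mark.parametrize("n_snps", [1, 2, 3])
def test_label_rule_exhaustive(n_snps):
    """All 4^n call combinations agree with the truth-table oracle."""
    snps = [f"s{i}" for i in range(n_snps)]
    fam = MarkerFamily(name="f", snp_ids=tuple(snps))
    for combo in itertools.product(list(SnpCall), repeat=n_snps):
        table = table_from_calls({"c": list(combo)}, snps)
        assert label_cultivar(table, fam, "c") is truth_table_label(combo)


@given(
    calls=st.lists(st.sampled_from(list(SnpCall)), min_size=1, max_size=4),
    flip=st.integers(min_value=0, max_value=3),
)
@settings(derandomize=True, max_examples=200)
def test_label_monotone_under_ref_to_alt_flip(calls, flip):
    """Flipping any HOM_REF to HOM_ALT never demotes ALTERNATE to REFERENCE."""
    snps = [f"s{i}" for i in range(len(calls))]
    fam = MarkerFamily(name="f", snp_ids=tuple(snps))
    before = label_cultivar(table_from_calls({"c": calls}, snps), fam, "c")
    flipped = list(calls)
    flipped[flip % len(calls)] = SnpCall.HOM_ALT
    after = label_cultivar(table_from_calls({"c": flipped}, snps), fam, "c")
    assert after is FamilyLabel.ALTERNATE
    if before is FamilyLabel.ALTERNATE:
        assert after is not FamilyLabel.REFERENCE


def test_label_unknown_snp_raises():
    table = table_from_calls({"c": [SnpCall.HOM_REF]}, ["s0"])
    fam = MarkerFamily(name="f", snp_ids=("s0", "missing_snp"))
    with pytest.raises(ValueError, match="absent"):
        label_cultivar(table, fam, "c")


# ---------------------------------------------------------------------------
# splitting


def _fake_images(cultivars, per=10):
    return {c: [f"{c}_img{i}" for i in range(per)] for c in cultivars}


def _labels(n_ref, n_alt):
    labels = {}
    for i in range(n_ref):
        labels[f"ref{i:03d}"] = FamilyLabel.REFERENCE
    for i in range(n_alt):
        labels[f"alt{i:03d}"] = FamilyLabel.ALTERNATE
    return labels


def test_split_half_of_minority_class():
    labels = _labels(10, 30)
    split = make_split(labels, _fake_images(labels), seed=0)
    by_class = split.test.groupby("label")["cultivar"].nunique()
    assert by_class["REFERENCE"] == 5 and by_class["ALTERNATE"] == 5
    train_classes = split.train.groupby("label")["cultivar"].nunique()
    assert train_classes["REFERENCE"] == 5 and train_classes["ALTERNATE"] == 25
    counts = split.test["label"].value_counts()
    assert counts["REFERENCE"] == counts["ALTERNATE"]


def test_split_symmetric_case():
    labels = _labels(4, 4)
    split = make_split(labels, _fake_images(labels), seed=1)
    assert split.test.groupby("label")["cultivar"].nunique().tolist() == [2, 2]


def test_split_deterministic_and_order_invariant():
    labels = _labels(6, 9)
    images = _fake_images(labels)
    a = make_split(labels, images, seed=7)
    b = make_split(labels, images, seed=7)
    pd.testing.assert_frame_equal(a.train, b.train)
    pd.testing.assert_frame_equal(a.test, b.test)
    shuffled_labels = dict(reversed(list(labels.items())))
    shuffled_images = dict(reversed(list(images.items())))
    c = make_split(shuffled_labels, shuffled_images, seed=7)
    pd.testing.assert_frame_equal(a.test.sort_values("image_id", ignore_index=True),
                                  c.test.sort_values("image_id", ignore_index=True))


def test_split_excluded_dropped_and_unsplittable():
    labels = _labels(3, 3)
    labels["het0"] = FamilyLabel.EXCLUDED
    split = make_split(labels, _fake_images(labels), seed=0)
    assert "het0" not in split.train_cultivars | split.test_cultivars
    with pytest.raises(ValueError, match="unsplittable"):
        make_split(_labels(1, 5), _fake_images(_labels(1, 5)), seed=0)


def test_split_disjoint_fuzz():
    rng = np.random.default_rng(0)
    for trial in range(100):
        n_ref = int(rng.integers(2, 12))
        n_alt = int(rng.integers(2, 12))
        labels = _labels(n_ref, n_alt)
        images = {c: [f"{c}_i{k}" for k in range(int(rng.integers(1, 6)))] for c in labels}
        split = make_split(labels, images, seed=int(rng.integers(0, 2**31)))
        assert not (split.train_cultivars & split.test_cultivars)
        counts = split.test["label"].value_counts()
        assert counts.get("REFERENCE", 0) == counts.get("ALTERNATE", 0)


def test_split_manifest_roundtrip(tmp_path):
    labels = _labels(4, 6)
    split = make_split(labels, _fake_images(labels), seed=3)
    path = tmp_path / "split.csv"
    split.to_manifest(path)
    again = DatasetSplit.from_manifest(path)
    assert again.seed == 3
    assert set(map(tuple, again.test.to_numpy())) == set(map(tuple, split.test.to_numpy()))


# ---------------------------------------------------------------------------
# balanced batches


def _train_frame(n_ref, n_alt):
    rows = [(f"r{i}", "cr", "REFERENCE") for i in range(n_ref)]
    rows += [(f"a{i}", "ca", "ALTERNATE") for i in range(n_alt)]
    return pd.DataFrame(rows, columns=["image_id", "cultivar", "label"])


def test_batches_balanced_even_size():
    train = _train_frame(100, 900)
    plan = plan_balanced_batches(train, batch_size=100, seed=0)
    for batch in plan.batches:
        n_ref = sum(b.startswith("r") for b in batch)
        assert n_ref == 50 and len(batch) == 100


def test_batches_odd_size_alternates_majority():
    plan = plan_balanced_batches(_train_frame(20, 20), batch_size=3, seed=0)
    extras = []
    for batch in plan.batches:
        n_ref = sum(b.startswith("r") for b in batch)
        assert abs(n_ref - (len(batch) - n_ref)) <= 1
        extras.append(n_ref > len(batch) - n_ref)
    assert any(extras) and not all(extras)


def test_batch_class_frequency_over_epoch():
    """Across one epoch the sampled class frequency is 1/2 within 1%."""
    train = _train_frame(50, 950)
    plan = plan_balanced_batches(train, batch_size=100, seed=1)
    flat = [iid for batch in plan.batches for iid in batch]
    freq_ref = np.mean([iid.startswith("r") for iid in flat])
    assert abs(freq_ref - 0.5) <= 0.01


def test_batches_resample_minority_and_validate():
    plan = plan_balanced_batches(_train_frame(5, 95), batch_size=20, seed=2)
    seen_ref = [iid for b in plan.batches for iid in b if iid.startswith("r")]
    assert len(seen_ref) == 50  # 5 distinct images re-sampled with replacement
    assert len(set(seen_ref)) == 5
    with pytest.raises(ValueError):
        plan_balanced_batches(_train_frame(5, 5), batch_size=1, seed=0)
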