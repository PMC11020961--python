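import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epitree.core_data import (
    FeatureAnnotation,
    FeatureKind,
    FeatureMatrix,
    PhenotypeVector,
    ValidationError,
    WeightMap,
    aggregate_genes,
    align,
    balanced_case_control,
    ld_r2,
    read_feature_matrix,
    select_window_snps,
    split_train_test,
    write_feature_matrix,
)
from tests.conftest import make_genotypes


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def test_feature_matrix_rejects_duplicates_and_bad_dosages():
    with pytest.raises(ValidationError, match="duplicate sample"):
        FeatureMatrix(["a", "a"], ["f"], [[1.0], [2.0]], "genotype")
    with pytest.raises(ValidationError, match="dosage"):
        FeatureMatrix(["a", "b"], ["f"], [[1.0], [3.0]], "genotype")
    with pytest.raises(ValidationError, match="shape"):
        FeatureMatrix(["a"], ["f", "g"], [[1.0]], "expression")


def test_phenotype_must_be_binary():
    with pytest.raises(ValidationError):
        PhenotypeVector(["a", "b"], [0, 2])


def test_align_joins_by_id_not_position():
    fm = FeatureMatrix(["a", "b", "c"], ["f"], [[1.0], [2.0], [0.0]], "genotype")
    ph = PhenotypeVector(["c", "a"], [1, 0])  # different order, b missing
    fm2, ph2 = align(fm, ph)
    assert fm2.sample_ids == ["a", "c"]
    assert ph2.y.tolist() == [0, 1]
    assert fm2.values[:, 0].tolist() == [1.0, 0.0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_tsv_round_trip_preserves_values(tmp_path, rng):
    X = rng.normal(size=(50, 20))
    fm = FeatureMatrix(
        [f"s{i}" for i in range(50)], [f"g{j}" for j in range(20)], X,
        "expression",
    )
    path = tmp_path / "m.tsv"
    write_feature_matrix(fm, path)
    back = read_feature_matrix(path)
    assert back.sample_ids == fm.sample_ids
    assert back.feature_ids == fm.feature_ids
    np.testing.assert_allclose(back.values, fm.values, atol=1e-12)


def test_plink_raw_dialect(tmp_path):
    path = tmp_path / "g.raw"
    path.write_text(
        "FID IID PAT MAT SEX PHENOTYPE rs1_A\n"
        "f1 ind1 0 0 1 2 1\n"
        "f2 ind2 0 0 2 1 2\n"
    )
    fm = read_feature_matrix(path, format="plink_raw")
    assert fm.feature_ids == ["rs1_A"]
    assert fm.sample_ids == ["ind1", "ind2"]
    assert fm.values[:, 0].tolist() == [1.0, 2.0]
    assert fm.feature_kind is FeatureKind.genotype


def test_plink_raw_malformed_header_names_column(tmp_path):
    path = tmp_path / "g.raw"
    path.write_text("FID IID PAT MAT SEX rs1_A\n1 1 0 0 1 2\n")
    with pytest.raises(ValidationError, match="PHENOTYPE"):
        read_feature_matrix(path, format="plink_raw")


def test_non_numeric_cell_reports_coordinates(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text("sample_id\tg1\ns1\t1.0\ns2\toops\n")
    with pytest.raises(ValidationError, match="oops.*s2.*g1"):
        read_feature_matrix(path)


def test_missing_entries_flagged_and_imputable(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text("sample_id\tg1\ns1\t0\ns2\tNA\ns3\t2\n")
    fm = read_feature_matrix(path)
    assert fm.has_missing
    with pytest.raises(ValidationError, match="missing"):
        fm.require_complete()
    imputed = read_feature_matrix(path, impute_missing=True)
    assert not imputed.has_missing
    assert imputed.values[1, 0] == pytest.approx(1.0)  # per-feature mean


# ---------------------------------------------------------------------------
# gene aggregation
# ---------------------------------------------------------------------------

def _weights(entries):
    return WeightMap.from_entries(entries)


def test_aggregate_hand_example():
    fm = FeatureMatrix(["s"], ["s1", "s2"], [[1.0, 2.0]], "genotype")
    expr, dropped = aggregate_genes(fm, _weights([("s1", "G", 2.0),
                                                  ("s2", "G", -1.0)]))
    assert expr.values[0, 0] == pytest.approx(0.0)
    assert expr.feature_kind is FeatureKind.expression
    assert dropped == []


def test_aggregate_zero_weights_and_dropped_report():
    fm = FeatureMatrix(["s"], ["s1"], [[2.0]], "genotype")
    expr, dropped = aggregate_genes(
        fm, _weights([("s1", "G", 0.0), ("sX", "G", 5.0)])
    )
    assert expr.values[0, 0] == 0.0
    assert dropped == ["sX"]


def test_aggregate_is_bilinear(rng):
    # exactly linear in the dosage/weight pairing: scaling the weights by c
    # scales every gene score by c, and scores decompose per-SNP
    fm = make_genotypes(30, 5, seed=1)
    coefs = [float(rng.normal()) for _ in range(5)]
    w = _weights([(f"rs{j + 1}", "G", coefs[j]) for j in range(5)])
    w3 = _weights([(f"rs{j + 1}", "G", 3 * coefs[j]) for j in range(5)])
    base, _ = aggregate_genes(fm, w)
    tripled, _ = aggregate_genes(fm, w3)
    np.testing.assert_allclose(tripled.values, 3 * base.values, atol=1e-12)
    per_snp = sum(
        aggregate_genes(fm, _weights([(f"rs{j + 1}", "G", coefs[j])]))[0].values
        for j in range(5)
    )
    np.testing.assert_allclose(per_snp, base.values, atol=1e-12)


def test_aggregate_empty_overlap_errors():
    fm = FeatureMatrix(["s"], ["s1"], [[1.0]], "genotype")
    with pytest.raises(ValidationError, match="empty aggregation"):
        aggregate_genes(fm, _weights([("other", "G", 1.0)]))


# ---------------------------------------------------------------------------
# sampling and splitting
# ---------------------------------------------------------------------------

def test_balanced_case_control_matches_design():
    n = 40000
    y = np.zeros(n, dtype=int)
    y[:19000] = 1
    ph = PhenotypeVector([f"s{i}" for i in range(n)], y)
    ids = balanced_case_control(ph, 15000, seed=3)
    assert len(ids) == 30000
    picked = ph.take_samples(ids)
    assert int(picked.y.sum()) == 15000
    assert balanced_case_control(ph, 15000, seed=3) == ids  # deterministic
    assert balanced_case_control(ph, 0, seed=3) == []
    with pytest.raises(ValidationError, match="insufficient"):
        balanced_case_control(ph, 25000, seed=3)


def test_split_matches_published_design():
    ids = [f"s{i}" for i in range(30000)]
    y = np.tile([0, 1], 15000)
    ph = PhenotypeVector(ids, y)
    split = split_train_test(ids, 2.0 / 15.0, seed=0, pheno=ph)
    assert len(split.train_ids) == 26000
    assert len(split.test_ids) == 4000
    test_y = ph.take_samples(split.test_ids).y
    assert int(test_y.sum()) == 2000  # stratified


def test_split_partitions_for_many_seeds():
    ids = [f"s{i}" for i in range(100)]
    for seed in range(100):
        split = split_train_test(ids, 0.5, seed=seed)
        assert not set(split.train_ids) & set(split.test_ids)
        assert sorted(split.train_ids + split.test_ids) == sorted(ids)
    with pytest.raises(ValueError):
        split_train_test(ids, 1.5, seed=0)


# ---------------------------------------------------------------------------
# windows and LD
# ---------------------------------------------------------------------------

def _annot(entries):
    return {e[0]: FeatureAnnotation(*e) for e in entries}


def test_window_selection_examples():
    fm = make_genotypes(5, 2, seed=0)
    annot = _annot([
        ("G", "chr16", 2_000_000, 2_010_000),
        ("rs1", "chr16", 1_500_000, 1_500_000),
        ("rs2", "chr15", 1_500_000, 1_500_000),
    ])
    assert select_window_snps(fm, annot, ["G"]) == ["rs1"]
    with pytest.raises(KeyError, match="G2"):
        select_window_snps(fm, annot, ["G2"])


def test_window_zero_matches_brute_force(rng):
    fm = make_genotypes(3, 100, seed=2)
    entries = [("G", "chr1", 5_000_000, 6_000_000)]
    positions = {}
    for j in range(100):
        pos = int(rng.integers(1, 10_000_000))
        chrom = "chr1" if rng.random() < 0.7 else "chr2"
        entries.append((f"rs{j + 1}", chrom, pos, pos))
        positions[f"rs{j + 1}"] = (chrom, pos)
    annot = _annot(entries)
    got = set(select_window_snps(fm, annot, ["G"], window_bp=0))
    expected = {
        s for s, (c, pos) in positions.items()
        if c == "chr1" and 5_000_000 <= pos <= 6_000_000
    }
    assert got == expected


def test_ld_r2_identity_complement_and_independence():
    r = np.random.default_rng(5)
    a = r.binomial(2, 0.4, size=10000).astype(float)
    b = r.binomial(2, 0.4, size=10000).astype(float)
    fm = FeatureMatrix(
        [f"s{i}" for i in range(10000)], ["a", "b", "a2", "comp"],
        np.column_stack([a, b, a, 2 - a]), "genotype",
    )
    assert ld_r2(fm, "a", "a2") == pytest.approx(1.0)
    assert ld_r2(fm, "a", "comp") == pytest.approx(1.0)  # affine recoding
    assert ld_r2(fm, "a", "b") < 0.01
    assert ld_r2(fm, "a", "b") == pytest.approx(ld_r2(fm, "b", "a"))
    mono = FeatureMatrix(["s1", "s2"], ["m", "a"], [[1, 0], [1, 2]], "genotype")
    with pytest.raises(ValidationError, match="monomorphic"):
        ld_r2(mono, "m", "a")


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_split_disjointness_property(seed):
    ids = [f"s{i}" for i in range(37)]
    split = split_train_test(ids, 0.3, seed=seed)
    assert len(split.train_ids) + len(split.test_ids) == 37
    assert not set(split.train_ids) & set(split.test_ids)
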