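"""Pair tables, negative sampling and stratified splitting."""

import itertools

import numpy as np
import pytest

from dualddi import (
    load_pair_table,
    make_pair,
    sample_negatives,
    stratified_split,
)
from dualddi.chem import parse_smiles, DrugRecord
from dualddi.pairs import write_pair_table


def library_of(n):
    smiles = ["C" * (i + 1) for i in range(n)]
    return [
        DrugRecord(drug_id=f"d{i}", smiles=s, graph=parse_smiles(s))
        for i, s in enumerate(smiles)
    ]


@pytest.fixture
def library():
    return library_of(6)


def test_pairs_are_unordered_records():
    assert make_pair("b", "a", 1) == make_pair("a", "b", 1)
    with pytest.raises(ValueError, match="self-pair"):
        make_pair("a", "a", 1)


def test_labeled_file_loads_all_rows(tmp_path, library):
    path = tmp_path / "pairs.csv"
    path.write_text("drug_a,drug_b,label\nd0,d1,1\nd0,d2,0\nd3,d4,1\n")
    pairs = load_pair_table(path, library)
    assert len(pairs) == 3
    assert [p.label for p in pairs] == [1, 0, 1]


def test_order_swapped_duplicates_collapse(tmp_path, library):
    path = tmp_path / "pairs.csv"
    path.write_text("drug_a,drug_b,label\nd0,d1,1\nd1,d0,1\n")
    assert len(load_pair_table(path, library)) == 1


def test_contradictory_duplicate_labels_rejected(tmp_path, library):
    path = tmp_path / "pairs.csv"
    path.write_text("drug_a,drug_b,label\nd0,d1,1\nd1,d0,0\n")
    with pytest.raises(ValueError, match="contradictory"):
        load_pair_table(path, library)


def test_unknown_id_rejected(tmp_path, library):
    path = tmp_path / "pairs.csv"
    path.write_text("drug_a,drug_b,label\nd0,zz,1\n")
    with pytest.raises(ValueError, match="zz"):
        load_pair_table(path, library)


def test_positives_only_file_gets_label_one(tmp_path, library):
    path = tmp_path / "pairs.csv"
    path.write_text("drug_a,drug_b\nd0,d1\nd2,d3\n")
    assert all(p.label == 1 for p in load_pair_table(path, library))


def test_pair_table_roundtrip(tmp_path, library):
    pairs = [make_pair("d0", "d1", 1), make_pair("d2", "d3", 0)]
    path = tmp_path / "pairs.csv"
    write_pair_table(pairs, path)
    assert load_pair_table(path, library) == pairs


def test_negatives_disjoint_from_positives_exhaustively():
    library = library_of(4)
    positives = [make_pair("d0", "d1", 1), make_pair("d0", "d2", 1),
                 make_pair("d1", "d2", 1)]
    negatives = sample_negatives(positives, library, ratio=1.0, seed=3)
    assert len(negatives) == 3
    pos_keys = {(p.drug_a, p.drug_b) for p in positives}
    for neg in negatives:
        assert neg.label == 0
        assert (neg.drug_a, neg.drug_b) not in pos_keys


def test_negatives_deterministic_given_seed():
    library = library_of(20)
    rng = np.random.default_rng(0)
    ids = [r.drug_id for r in library]
    positives = [
        make_pair(*rng.choice(ids, size=2, replace=False), 1) for _ in range(30)
    ]
    positives = list(dict.fromkeys(positives))
    a = sample_negatives(positives, library, 1.0, seed=11)
    b = sample_negatives(positives, library, 1.0, seed=11)
    c = sample_negatives(positives, library, 1.0, seed=12)
    assert a == b
    assert set(a) != set(c)


def test_complete_positive_graph_leaves_no_negatives():
    library = library_of(4)
    positives = [
        make_pair(a, b, 1)
        for a, b in itertools.combinations([r.drug_id for r in library], 2)
    ]
    with pytest.raises(ValueError, match="non-positive"):
        sample_negatives(positives, library, 1.0, seed=0)


def test_split_counts_match_six_two_two():
    pairs = [make_pair(f"p{i}", f"q{i}", 1) for i in range(10)]
    pairs += [make_pair(f"r{i}", f"s{i}", 0) for i in range(10)]
    split = stratified_split(pairs, (0.6, 0.2, 0.2), seed=5)
    sizes = {name: len(split.partition(name)) for name in ("train", "valid", "test")}
    assert sizes == {"train": 12, "valid": 4, "test": 4}
    for name in sizes:
        part = split.partition(name)
        assert sum(p.label for p in part) == len(part) // 2  # 6/2/2 positives


def test_split_deterministic_and_exhaustive():
    pairs = [make_pair(f"p{i}", f"q{i}", i % 2) for i in range(40)]
    a = stratified_split(pairs, (0.6, 0.2, 0.2), seed=9)
    b = stratified_split(pairs, (0.6, 0.2, 0.2), seed=9)
    assert a.assignment == b.assignment
    assigned = [p for name in ("train", "valid", "test") for p in a.partition(name)]
    assert sorted(assigned) == sorted(pairs)


def test_bad_ratios_rejected():
    pairs = [make_pair(f"p{i}", f"q{i}", i % 2) for i in range(10)]
    with pytest.raises(ValueError, match="sum to 1"):
        stratified_split(pairs, (0.5, 0.5, 0.1), seed=0)


def test_class_smaller_than_partition_count_rejected():
    pairs = [make_pair(f"p{i}", f"q{i}", 1) for i in range(8)]
    pairs += [make_pair("x", "y", 0)]
    with pytest.raises(ValueError, match="fewer"):
        stratified_split(pairs, (0.6, 0.2, 0.2), seed=0)
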