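import numpy as np
import pytest

from neuropep import (
    LabeledDataset,
    Peptide,
    aac,
    assign_five_folds,
    build_similar_negatives,
    load_dataset,
    sample_random_negatives,
    save_dataset,
    split_train_validation,
)
from neuropep.fixtures import generate_background_peptides, generate_signal_peptides, SignalSpec

from conftest import random_peptides


def make_dataset(n_pos=20, n_neg=20, seed=0):
    rng = np.random.default_rng(seed)
    pos = random_peptides(n_pos, rng, prefix="pos")
    neg = random_peptides(n_neg, rng, prefix="neg")
    return LabeledDataset(positives=pos, negatives=neg)


class TestLabeledDataset:
    def test_class_overlap_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            LabeledDataset(
                positives=[Peptide("a", "ACDEF")],
                negatives=[Peptide("b", "ACDEF")],
            )

    def test_labels_assigned(self):
        ds = make_dataset(3, 3)
        assert all(p.label == "positive" for p in ds.positives)
        assert all(p.label == "negative" for p in ds.negatives)


class TestRandomNegatives:
    def test_lengths_match_positive_multiset(self):
        rng = np.random.default_rng(1)
        background = random_peptides(30, rng, min_len=60, max_len=120, prefix="bg")
        positives = random_peptides(50, rng, min_len=5, max_len=40, prefix="p")
        negs = sample_random_negatives(background, positives, 50, seed=7)
        assert len(negs) == 50
        pos_lengths = {len(p) for p in positives}
        assert all(len(n) in pos_lengths for n in negs)
        assert len({n.sequence for n in negs}) == 50  # distinct
        pos_seqs = {p.sequence for p in positives}
        assert not any(n.sequence in pos_seqs for n in negs)

    def test_n_zero(self):
        rng = np.random.default_rng(1)
        assert sample_random_negatives(
            random_peptides(3, rng), random_peptides(3, rng), 0, seed=0
        ) == []

    def test_infeasible_background(self):
        with pytest.raises(ValueError, match="shorter"):
            sample_random_negatives(
                [Peptide("bg", "ACD")], [Peptide("p", "ACDEFGHIKL")], 5, seed=0
            )

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(2)
        background = random_peptides(20, rng, min_len=50, max_len=100)
        positives = random_peptides(20, rng, prefix="p")
        a = sample_random_negatives(background, positives, 20, seed=3)
        b = sample_random_negatives(background, positives, 20, seed=3)
        assert [x.sequence for x in a] == [x.sequence for x in b]


class TestSimilarNegatives:
    def test_identical_composition_chosen_at_distance_zero(self):
        pos = [Peptide("p", "AACC")]
        pool = [Peptide("far", "GGGG"), Peptide("near", "CACA")]
        chosen = build_similar_negatives(pos, pool)
        assert chosen[0].sequence == "CACA"
        assert np.linalg.norm(aac(pos[0]).values - aac(chosen[0]).values) == 0.0

    def test_two_coordinate_distance(self):
        d = np.linalg.norm(
            aac(Peptide("a", "AAAA")).values - aac(Peptide("b", "CCCC")).values
        )
        assert d == pytest.approx(np.sqrt(2) * 100, abs=1e-9)

    def test_without_replacement_perfect_matching(self):
        pos = [Peptide(f"p{i}", s) for i, s in enumerate(["AAAA", "CCCC", "GGGG"])]
        pool = [Peptide(f"c{i}", s) for i, s in enumerate(["GGGA", "AAAC", "CCCG"])]
        chosen = build_similar_negatives(pos, pool)
        assert len({c.id for c in chosen}) == 3

    def test_pool_too_small(self):
        with pytest.raises(ValueError, match="pool"):
            build_similar_negatives(
                [Peptide("a", "AA"), Peptide("b", "CC")], [Peptide("c", "GG")]
            )

    def test_hard_negatives_closer_than_random(self):
        # matched pool members must be nearer in composition than a random draw
        pos = generate_signal_peptides(40, SignalSpec(seed=5))
        pool = generate_background_peptides(200, seed=6, id_prefix="pool")
        matched = build_similar_negatives(pos, pool)
        rng = np.random.default_rng(7)
        random_pick = [pool[i] for i in rng.choice(len(pool), 40, replace=False)]
        def mean_dist(negs):
            return np.mean([
                np.linalg.norm(aac(p).values - aac(n).values)
                for p, n in zip(pos, negs)
            ])
        assert mean_dist(matched) < mean_dist(random_pick)


class TestSplitAndFolds:
    def test_split_arithmetic_875(self):
        ds = make_dataset(875, 875, seed=9)
        ds = split_train_validation(ds, 0.8, seed=1)
        pos_tr, neg_tr = ds.subset("train")
        pos_va, neg_va = ds.subset("validation")
        assert len(pos_tr) == len(neg_tr) == 700
        assert len(pos_va) == len(neg_va) == 175

    def test_fraction_half(self):
        ds = split_train_validation(make_dataset(4, 4), 0.5, seed=0)
        pos_tr, _ = ds.subset("train")
        pos_va, _ = ds.subset("validation")
        assert len(pos_tr) == len(pos_va) == 2

    def test_five_folds_partition_700(self):
        ds = make_dataset(875, 875, seed=10)
        ds = assign_five_folds(split_train_validation(ds, seed=2), seed=2)
        pos_tr, neg_tr = ds.subset("train")
        for group in (pos_tr, neg_tr):
            sizes = np.bincount([ds.folds[p.id] for p in group], minlength=6)[1:]
            assert list(sizes) == [140] * 5
        assert set(ds.folds) == {p.id for p in pos_tr + neg_tr}

    def test_fold_sizes_differ_by_at_most_one(self):
        ds = make_dataset(23, 17, seed=3)
        ds = assign_five_folds(split_train_validation(ds, seed=3), seed=3)
        for group in ds.subset("train"):
            sizes = np.bincount([ds.folds[p.id] for p in group], minlength=6)[1:]
            assert sizes.max() - sizes.min() <= 1

    def test_same_seed_identical_assignments(self):
        ds = make_dataset(50, 50, seed=4)
        a = assign_five_folds(split_train_validation(ds, seed=8), seed=8)
        b = assign_five_folds(split_train_validation(ds, seed=8), seed=8)
        assert a.split == b.split and a.folds == b.folds

    def test_too_few_to_split(self):
        with pytest.raises(ValueError):
            split_train_validation(
                LabeledDataset(positives=[Peptide("a", "ACD")],
                               negatives=[Peptide("b", "CDE"), Peptide("c", "DEF")])
            )


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path):
        ds = make_dataset(20, 20, seed=5)
        ds = assign_five_folds(split_train_validation(ds, seed=5), seed=5)
        save_dataset(ds, tmp_path / "bench")
        back = load_dataset(tmp_path / "bench")
        assert {p.sequence for p in back.positives} == {p.sequence for p in ds.positives}
        assert {p.sequence for p in back.negatives} == {p.sequence for p in ds.negatives}
        assert back.split == ds.split
        assert back.folds == ds.folds
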